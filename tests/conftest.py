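import numpy as np
import pytest

from dermseg import SyntheticParams, generate_sample


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_sample():
    """One deterministic lesion-bearing sample under default conditions."""
    return generate_sample(SyntheticParams(seed=7), class_index=0)


def flood_fill_components(mask):
    """Independent connected-component oracle (8-connectivity BFS)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, pix = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                pix.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(pix)
    return comps
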