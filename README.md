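# dermseg

Two-phase localization and classification of erythematous skin disease in
ordinary camera photographs.

Dermatological screening is still mostly done by eye, and erythema — skin
redness from increased superficial hemoglobin — is both one of the most
common disease signs and one of the easiest to overlook or mislabel.
`dermseg` implements a computer-aided-diagnosis pipeline that first finds
abnormal skin, then names the disease in each found region, so a single
photograph can yield several localized diagnoses with confidences. It is
aimed at researchers building or evaluating such pipelines: every stage is
a scikit-learn-style estimator, every experiment is reproducible from a
seed, and a built-in synthetic-skin generator provides exact ground truth
so the whole pipeline is testable without clinical data.

## The method

**1. Chromophore decomposition.** Skin color is dominated by two absorbers,
melanin and hemoglobin. Under the attenuation model the per-pixel optical
density is a linear mixture

```
L(x,y) = d_m · q_m(x,y) + d_h · q_h(x,y) + Δ,     L = −log((I+1)/256)
```

where `d_m`, `d_h` are channelwise density vectors and `q_m`, `q_h` scalar
quantity fields. A two-component ICA over the pixel cloud estimates the
mixing directions `D̄ = [d_m; d_h]`; quantities follow from the
pseudo-inverse, shifted by the per-component minimum `E` so they are
non-negative:

```
[q_m, q_h] = D̄⁺ L − E,     E = min_{x,y} (D̄⁺ L)
```

Each constituent renders back to an image via `I = 256·exp(−d·q) − 1`: the
hemoglobin image shows erythema stripped of pigmentation and lighting, the
melanin image the reverse.

**2. Segmentation.** An encoder–decoder network with skip connections
(U-Net-shaped, zero-padded so output resolution equals input) consumes the
stacked original + hemoglobin + melanin images (9 channels) and produces a
binary abnormal-skin mask (white = abnormal).

**3. Localization.** Connected mask clusters are contour-traced, wrapped in
convex hulls and axis-aligned boxes, padded, squared, and cropped from the
original photograph.

**4. Classification.** Each crop is classified independently
(sensitivity/specificity/F1/AUC weighted by class counts; Top-n accuracy),
with the Dice coefficient `2TP/((TP+FP)+(TP+FN))` and the symmetric
Hausdorff distance `H(X,Y) = max(h(X,Y), h(Y,X))`,
`h(X,Y) = max_x min_y ‖x−y‖`, scoring segmentation.

The networks run on a small numpy layer library with hand-written
backpropagation — no GPU framework required — with a miniature profile
(96×96, depth 3) that trains in minutes on one CPU and a full-scale profile
(304×304, depth 4) for real data. See `docs/methods.md` for the model
details, the synthetic generator's assumptions, and design rationale.

## Worked example

```python
import numpy as np
from dermseg import (SyntheticParams, generate_sample, rgb_to_optical_density,
                     estimate_density_matrix, compute_quantity_maps,
                     localize, LocalizationParams)

params = SyntheticParams(seed=0, noise_sd=0.005)
sample = generate_sample(params, class_index=0)   # image + exact ground truth
od = rgb_to_optical_density(sample.image)
dm = estimate_density_matrix(od, rng_seed=0)      # blind ICA estimate
print("estimated d_h :", dm.d_h.round(3))
print("true d_h      :", sample.density[1].round(3))
q = compute_quantity_maps(od, dm)
r = np.corrcoef(q.q_h.ravel(), sample.q_h.ravel())[0, 1]
print(f"corr(q_h, truth) = {r:.4f}")
for c in localize(sample.image, sample.mask, LocalizationParams(target_size=64)):
    print(f"lesion bbox={c.bbox} area={c.area}px crop={c.crop.shape}")
```

prints

```
estimated d_h : [0.068 0.756 0.651]
true d_h      : [0.1   0.752 0.652]
corr(q_h, truth) = 0.9983
lesion bbox=(25, 48, 49, 72) area=273px crop=(64, 64, 3)
lesion bbox=(60, 55, 79, 74) area=168px crop=(64, 64, 3)
```

The blind estimate of the hemoglobin density vector matches the generator's
truth to within a few degrees, the recovered hemoglobin quantity field
correlates with truth at r = 0.998, and the two injected lesions come back
as two square, classifier-ready crops in original-image coordinates.

The same flow is available from the shell: `dermseg synth`, `dermseg
decompose`, `dermseg train-seg` / `predict-seg`, `dermseg train-clf` /
`classify`, `dermseg analyze --image X.png --seg SEGDIR --clf CLFDIR --out
report.json`, `dermseg evaluate-seg` / `evaluate-clf`, and `dermseg
experiment` for the multi-arm protocol below.

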