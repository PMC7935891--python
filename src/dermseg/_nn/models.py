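"""Network graphs: a U-Net-style encoder-decoder and a small CNN classifier.

Both are plain-numpy graphs built from the layers in this subpackage; the
forward/backward wiring (skip connections, channel concatenation) is explicit.
Weights serialize to/from a flat dict of arrays (saved as .npz).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, GlobalAvgPool, Linear, MaxPool2d, ReLU, UpsampleNearest2d, sigmoid, softmax


class _ConvBlock:
    """conv-relu-conv-relu."""

    def __init__(self, ci, co, rng):
        self.c1 = Conv2d(ci, co, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(co, co, 3, rng)
        self.r2 = ReLU()
        self.layers = [self.c1, self.r1, self.c2, self.r2]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def params(self):
        out = []
        for i, l in enumerate(self.layers):
            for name, v, gr in l.params():
                out.append((f"l{i}.{name}", v, gr))
        return out


class UNet:
    """Encoder-decoder with skip connections and same-size output.

    ``depth`` down-sampling stages halve the resolution each; the decoder
    mirrors them with nearest-neighbor upsampling, concatenating the
    same-resolution encoder features. Zero-padded 3x3 convolutions keep the
    output spatial size equal to the input's. The head is a 1x1 convolution
    producing one logit per pixel; ``forward`` returns probabilities.
    """

    def __init__(self, in_channels=9, depth=3, base_channels=8, seed=0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.depth = depth
        self.base_channels = base_channels
        chans = [base_channels * (2 ** i) for i in range(depth)]
        self.enc = []
        ci = in_channels
        for co in chans:
            self.enc.append(_ConvBlock(ci, co, rng))
            ci = co
        self.pools = [MaxPool2d() for _ in range(depth)]
        self.bottleneck = _ConvBlock(chans[-1], chans[-1] * 2, rng)
        self.ups = []
        self.dec = []
        ci = chans[-1] * 2
        for co in reversed(chans):
            self.ups.append((UpsampleNearest2d(), Conv2d(ci, co, 3, rng), ReLU()))
            self.dec.append(_ConvBlock(co * 2, co, rng))  # *2 from skip concat
            ci = co
        self.head = Conv2d(chans[0], 1, 1, rng)

    # -- graph execution ----------------------------------------------------
    def forward(self, x, train=True):
        """x: (n, c, h, w) float32 in [0,1]; returns logits (n, 1, h, w)."""
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"spatial dims must be divisible by {2 ** self.depth}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for (up, conv, relu), blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = relu.forward(conv.forward(up.forward(x, train), train), train)
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        return self.head.forward(x, train)

    def backward_full(self, grad):
        """Full backward pass; grad w.r.t. the head logits."""
        g = self.head.backward(grad)
        skip_grads = {}
        n_dec = len(self.dec)
        for i in range(n_dec - 1, -1, -1):
            up, conv, relu = self.ups[i]
            blk = self.dec[i]
            g = blk.backward(g)
            ch = self._skip_channels[i]
            skip_ch = g.shape[1] - ch
            # encoder level for dec[i]: depth-1-i
            skip_grads[self.depth - 1 - i] = g[:, :skip_ch]
            g = up.backward(conv.backward(relu.backward(g[:, skip_ch:])))
        g = self.bottleneck.backward(g)
        for lvl in range(self.depth - 1, -1, -1):
            g = self.pools[lvl].backward(g)
            g = g + skip_grads[lvl]
            g = self.enc[lvl].backward(g)
        return g

    def predict_proba(self, x):
        return sigmoid(self.forward(x.astype(np.float32), train=False))

    # -- parameters ---------------------------------------------------------
    def params(self):
        out = []
        for i, blk in enumerate(self.enc):
            out += [(f"enc{i}.{n}", v, g) for n, v, g in blk.params()]
        out += [(f"bott.{n}", v, g) for n, v, g in self.bottleneck.params()]
        for i, (up, conv, relu) in enumerate(self.ups):
            out += [(f"up{i}.{n}", v, g) for n, v, g in conv.params()]
        for i, blk in enumerate(self.dec):
            out += [(f"dec{i}.{n}", v, g) for n, v, g in blk.params()]
        out += [(f"head.{n}", v, g) for n, v, g in self.head.params()]
        return out

    def state_dict(self):
        return {name: v.copy() for name, v, _ in self.params()}

    def load_state_dict(self, state):
        for name, v, _ in self.params():
            v[...] = state[name]


class SmallCNN:
    """Three conv-relu-pool blocks, global average pooling, linear head.

    The compact classifier profile: adequate for small crops and CPU
    training. ``forward`` returns class logits.
    """

    def __init__(self, in_channels=3, n_classes=3, base_channels=8, seed=0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.n_classes = n_classes
        c = base_channels
        self.layers = [
            Conv2d(in_channels, c, 3, rng), ReLU(), MaxPool2d(),
            Conv2d(c, 2 * c, 3, rng), ReLU(), MaxPool2d(),
            Conv2d(2 * c, 4 * c, 3, rng), ReLU(), MaxPool2d(),
            GlobalAvgPool(),
        ]
        self.fc = Linear(4 * c, n_classes, rng)

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return self.fc.forward(x, train)

    def backward_full(self, grad):
        g = self.fc.backward(grad)
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def predict_proba(self, x):
        return softmax(self.forward(x.astype(np.float32), train=False))

    def params(self):
        out = []
        for i, l in enumerate(self.layers):
            out += [(f"l{i}.{n}", v, g) for n, v, g in l.params()]
        out += [(f"fc.{n}", v, g) for n, v, g in self.fc.params()]
        return out

    def state_dict(self):
        return {name: v.copy() for name, v, _ in self.params()}

    def load_state_dict(self, state):
        for name, v, _ in self.params():
            v[...] = state[name]
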