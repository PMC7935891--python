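"""Optimizers and the step learning-rate schedule.

All optimizers update parameter arrays in place from the gradient buffers the
layers expose. Weight decay is decoupled L2 added to the gradient.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params, lr, weight_decay=0.0):
        # params: list of (name, value, grad) triples; values updated in place
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def step(self):  # pragma: no cover - interface
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr, weight_decay=0.0, momentum=0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = float(momentum)
        self._vel = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self):
        for (name, v, g), vel in zip(self.params, self._vel):
            grad = g + self.weight_decay * v
            vel *= self.momentum
            vel += grad
            v -= self.lr * vel


class Adam(Optimizer):
    def __init__(self, params, lr, weight_decay=0.0, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        super().__init__(params, lr, weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(v) for _, v, _ in self.params]
        self._v = [np.zeros_like(v) for _, v, _ in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for (name, v, g), m, s in zip(self.params, self._m, self._v):
            grad = g + self.weight_decay * v
            m *= b1
            m += (1 - b1) * grad
            s *= b2
            s += (1 - b2) * grad * grad
            mhat = m / (1 - b1 ** self._t)
            shat = s / (1 - b2 ** self._t)
            v -= self.lr * mhat / (np.sqrt(shat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr, weight_decay=0.0, alpha=0.99, eps=1e-8):
        super().__init__(params, lr, weight_decay)
        self.alpha, self.eps = alpha, eps
        self._s = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self):
        for (name, v, g), s in zip(self.params, self._s):
            grad = g + self.weight_decay * v
            s *= self.alpha
            s += (1 - self.alpha) * grad * grad
            v -= self.lr * grad / (np.sqrt(s) + self.eps)


def make_optimizer(name, params, lr, weight_decay=0.0, momentum=0.9):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr, weight_decay)
    if name == "rmsprop":
        return RMSprop(params, lr, weight_decay)
    if name == "sgd":
        return SGD(params, lr, weight_decay, momentum)
    raise ValueError(f"unknown optimizer '{name}'")


def scheduled_lr(base_lr, epoch, decay_factor, decay_every):
    """Step schedule: lr is multiplied by decay_factor every decay_every
    completed epochs (epoch is 0-based)."""
    if decay_every <= 0:
        return base_lr
    return base_lr * (decay_factor ** (epoch // decay_every))
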