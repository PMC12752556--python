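"""AdamW with an optional cosine-annealed learning rate."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "cosine_lr"]


def cosine_lr(lr0: float, step: int, total: int) -> float:
    if total <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * step / (total - 1)))


class AdamW:
    """Decoupled weight decay Adam over a list of Modules."""

    def __init__(self, modules, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.modules = [m for m in modules if m.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in mod.params.items()}
                  for mod in self.modules]
        self.v = [{k: np.zeros_like(v) for k, v in mod.params.items()}
                  for mod in self.modules]

    def zero_grad(self):
        for mod in self.modules:
            mod.zero_grad()

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for mod, m, v in zip(self.modules, self.m, self.v):
            for k, p in mod.params.items():
                g = mod.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                upd = (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
                if self.wd and p.ndim > 1:  # no decay on biases/norm params
                    upd = upd + self.wd * p
                p -= (lr * upd).astype(p.dtype)
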