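"""Optimizers for the manual-backprop modules."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Adam:
    """Adam with GAN-lineage defaults (beta1=0.5).

    beta1=0.9 is the textbook value but destabilizes alternating adversarial
    updates; 0.5 is the standard choice in the pix2pix/CUT family.
    """

    def __init__(self, params: list[Parameter], lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for tgt, src in zip(self.m, state["m"]):
            tgt[...] = src
        for tgt, src in zip(self.v, state["v"]):
            tgt[...] = src
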