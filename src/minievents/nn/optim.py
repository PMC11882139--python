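"""Adam optimizer with the AMSGrad variant."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamAMSGrad"]


class AdamAMSGrad:
    """Adam with AMSGrad max-normalized second moments.

    Only parameters flagged trainable are updated; moment buffers are
    keyed by parameter identity so freezing mid-run is safe.
    """

    def __init__(self, params: list, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._vhat = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v, vhat in zip(self.params, self._m, self._v, self._vhat):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            np.maximum(vhat, v, out=vhat)
            mhat = m / bias1
            vcorr = vhat / bias2
            p.value -= self.lr * mhat / (np.sqrt(vcorr) + self.eps)
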