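"""Adam optimizer over named parameter arrays."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the conventional defaults (beta1=0.9, beta2=0.999, eps=1e-8).

    The learning rate is passed to :meth:`step` so a schedule can vary it
    between epochs without touching optimizer state.
    """

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, named_params, named_grads, lr: float) -> None:
        """Update parameters in place.

        Parameters
        ----------
        named_params, named_grads : dict[str, ndarray]
            Matching keys; parameters are modified in place.
        lr : float
            Learning rate for this step.
        """
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for key, p in named_params.items():
            g = named_grads[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= (lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
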