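"""Binary cross-entropy on logits, numerically stable."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=z.dtype)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean per-pixel binary cross entropy and its gradient w.r.t. logits.

    Uses the log-sum-exp form ``max(z,0) - z*y + log(1 + exp(-|z|))`` so large
    logits of either sign cannot overflow.

    Returns
    -------
    loss : float
    dlogits : ndarray, same shape as ``logits``
    """
    z = logits
    y = targets.astype(z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    dlogits = (sigmoid(z) - y) / n
    return float(loss.mean()), dlogits


def bce_with_logits_per_sample(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-sample mean pixel BCE for an (N, 1, H, W) batch."""
    z = logits
    y = targets.astype(z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return loss.reshape(loss.shape[0], -1).mean(axis=1)
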