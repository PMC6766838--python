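"""Xavier (Glorot) uniform weight initialization.

Weights are drawn from U(-a, a) with a = sqrt(6 / (fan_in + fan_out)), which
gives variance 2 / (fan_in + fan_out) and keeps layer output variance roughly
constant through depth.  For a convolution with a k x k kernel,
fan_in = C_in * k^2 and fan_out = C_out * k^2.
"""

from __future__ import annotations

import numpy as np


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator,
                   fan_in: int, fan_out: int, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def conv_fans(weight_shape: tuple[int, ...], transposed: bool = False):
    """(fan_in, fan_out) for a conv weight tensor.

    Plain conv weights are (C_out, C_in, k, k); transposed-conv weights are
    (C_in, C_out, k, k).
    """
    if transposed:
        cin, cout = weight_shape[0], weight_shape[1]
    else:
        cout, cin = weight_shape[0], weight_shape[1]
    receptive = int(np.prod(weight_shape[2:])) if len(weight_shape) > 2 else 1
    return cin * receptive, cout * receptive
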