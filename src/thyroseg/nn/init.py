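"""Weight initialization helpers."""

from __future__ import annotations

import numpy as np


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """He initialization for ReLU networks: N(0, sqrt(2/fan_in)).

    For conv weights (Cout, Cin/g, kh, kw) fan_in = Cin/g * kh * kw.
    """
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)
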