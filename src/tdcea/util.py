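"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_half_up"]


def round_half_up(x, ndigits: int = 0):
    """Round half away from zero (the convention used for all reported figures).

    Works on scalars and numpy arrays.  Internal model arithmetic is never
    rounded; this is applied only at the reporting boundary and for the few
    published parameter roundings the model reproduces deliberately.
    """
    scale = 10.0 ** ndigits
    if isinstance(x, np.ndarray):
        out = np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale
        return out
    v = math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)
    return int(v) if ndigits <= 0 else v
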