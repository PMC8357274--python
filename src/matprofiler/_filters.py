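"""Shared smoothing primitives.

A linear (order-1) Savitzky-Golay filter evaluated at the centre of a
symmetric window on a uniform grid is identical to a centred moving
average.  The implementation below exploits that identity and shrinks the
window symmetrically near the ends of the record, so that constant and
straight-line inputs are reproduced exactly everywhere, including at the
endpoints.
"""

from __future__ import annotations

import numpy as np


def centered_moving_mean(values: np.ndarray, half_width: int, axis: int = -1) -> np.ndarray:
    """Symmetric moving average with shrink-to-fit endpoint windows.

    Equivalent to an order-1 Savitzky-Golay smoother of window
    ``2 * half_width + 1`` points evaluated at the window centre.  Works on
    the given axis of an n-d array.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    arr = np.asarray(values, dtype=float)
    if half_width == 0:
        return arr.copy()
    arr = np.moveaxis(arr, axis, -1)
    n = arr.shape[-1]
    if 2 * half_width + 1 > n:
        raise ValueError(
            f"smoothing window of {2 * half_width + 1} points exceeds record length {n}"
        )
    # subtracting a per-record baseline keeps constant inputs exactly constant
    base = arr[..., :1]
    resid = arr - base
    # prepend a zero so cs[..., j] is the sum of the first j samples
    cs = np.concatenate([np.zeros(arr.shape[:-1] + (1,)), np.cumsum(resid, axis=-1)], axis=-1)
    out = np.empty_like(arr)
    for i in range(n):
        hw = min(half_width, i, n - 1 - i)
        out[..., i] = (cs[..., i + hw + 1] - cs[..., i - hw]) / (2 * hw + 1)
    return np.moveaxis(base + out, -1, axis)
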