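"""Anisotropic binary median filtering of the thresholded stack.

Somas are quasi-spherical while myelin sheaths are thin and linear, so a
wide-in-plane, shallow-in-depth median window (default 11 x 11 x 3) erases
filaments and impulsive noise but preserves soma interiors. On a binary
volume the median is a strict majority vote; the default window holds
11*11*3 = 363 voxels (odd), so ties cannot occur. The filter runs on each
timepoint independently and treats out-of-volume voxels as background
(zero-padding), which never creates foreground at the borders.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d


def median_filter_3d(binary: np.ndarray, window: tuple[int, int, int] = (11, 11, 3)) -> np.ndarray:
    """Binary median (strict majority) over a centered wx*wy*wz window, per timepoint.

    Parameters
    ----------
    binary
        4D array in (x, y, z, t) with values in {0, 1}.
    window
        Odd window extents (wx, wy, wz).

    Returns
    -------
    uint8 array of the same shape; a voxel is 1 iff more than half of the
    in-window voxels (zero-padded at borders) are 1.
    """
    binary = np.asarray(binary)
    if binary.ndim != 4:
        raise ValueError(f"expected 4D (x, y, z, t) input, got ndim={binary.ndim}")
    vals = np.unique(binary)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("input must be binary (values in {0, 1})")
    window = tuple(int(w) for w in window)
    if len(window) != 3 or any(w < 1 or w % 2 == 0 for w in window):
        raise ValueError(f"window extents must be odd and >= 1, got {window}")

    wx, wy, wz = window
    volume = wx * wy * wz
    out = np.empty(binary.shape, dtype=np.uint8)
    for t in range(binary.shape[3]):
        counts = binary[..., t].astype(np.int32)
        # separable integer box sums: exact, zero-padded
        counts = correlate1d(counts, np.ones(wx, dtype=np.int32), axis=0, mode="constant", cval=0)
        counts = correlate1d(counts, np.ones(wy, dtype=np.int32), axis=1, mode="constant", cval=0)
        counts = correlate1d(counts, np.ones(wz, dtype=np.int32), axis=2, mode="constant", cval=0)
        out[..., t] = (2 * counts > volume)
    return out
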