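"""In-plane rigid resampling shared by the phantom generator and the motion corrector."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _rotation(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def resample_slice(
    img: np.ndarray,
    dx: float,
    dy: float,
    theta: float,
    inverse: bool = False,
    order: int = 1,
) -> np.ndarray:
    """Resample a 2D slice under an in-plane rigid transform.

    The forward map rotates the content by ``theta`` degrees about the slice
    centre, then translates by ``(dx, dy)`` voxels along the array axes.
    ``inverse=True`` applies the inverse map (undoes the forward motion).
    Bilinear interpolation by default; edge values are extended outward.
    """
    if dx == 0.0 and dy == 0.0 and theta == 0.0:
        return img.copy()
    c = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
    t = np.array([dx, dy], dtype=float)
    R = _rotation(theta)
    if inverse:
        # output(o) = img(F(o)) = R(o - c) + c + t
        A, offset = R, c + t - R @ c
    else:
        # output(o) = img(F^{-1}(o)) = R^T(o - c - t) + c
        A, offset = R.T, c - R.T @ (c + t)
    return ndimage.affine_transform(img, A, offset=offset, order=order, mode="nearest")
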