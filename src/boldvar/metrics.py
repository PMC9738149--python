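"""Temporal-variance and spatial-variance statistics of an intrinsic BOLD VOI.

Temporal variance (TV): sample standard deviation over time of the VOI-mean
signal after unity-mean normalisation.  Spatial variance (SV): sample standard
deviation across VOI voxels of per-voxel percent amplitude fluctuation after
dividing by the across-voxel mean.  Both are dimensionless and invariant to
global intensity rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import BoldSeries, VoiMask

log = logging.getLogger(__name__)

#: Supported per-voxel fluctuation conventions: mean absolute deviation
#: (percent-amplitude-fluctuation literature) or sample SD, both relative to
#: the voxel's temporal mean and expressed in percent.
PAF_CONVENTIONS = ("mad", "sd")

#: Mean PAF (percent) below this is float rounding of a constant VOI, not signal.
PAF_ZERO_TOL = 1e-10


@dataclass(frozen=True)
class VarianceMetrics:
    temporal_variance: float
    spatial_variance: float
    n_voxels: int
    n_frames: int
    tissue: str
    n_excluded_voxels: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.temporal_variance) and self.temporal_variance >= 0):
            raise ValueError("temporal_variance must be finite and nonnegative")
        if not (np.isfinite(self.spatial_variance) and self.spatial_variance >= 0):
            raise ValueError("spatial_variance must be finite and nonnegative")


def _mask_stack(series: BoldSeries, masks) -> np.ndarray:
    """Normalise a mask argument to a boolean per-frame stack (x, y, z, t)."""
    nt = series.n_frames
    if isinstance(masks, VoiMask):
        return np.repeat(masks.data[..., None], nt, axis=3)
    arr = np.asarray(masks).astype(bool)
    if arr.ndim == 3:
        return np.repeat(arr[..., None], nt, axis=3)
    if arr.shape != series.data.shape:
        raise ValueError(f"mask stack shape {arr.shape} != series shape {series.data.shape}")
    return arr


def volume_mean_course(series: BoldSeries, masks) -> np.ndarray:
    """Mean in-mask intensity of each frame.

    ``masks`` may be a static :class:`VoiMask` (propagated to every frame) or
    a per-frame boolean stack.
    """
    stack = _mask_stack(series, masks)
    counts = stack.sum(axis=(0, 1, 2))
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"empty mask at frame {empty[0]}")
    return (series.data * stack).sum(axis=(0, 1, 2)) / counts


def normalize_unity_mean(x: np.ndarray) -> np.ndarray:
    """Divide a time course by its own mean so the result has mean 1.

    Removes arbitrary scanner gain; rejects non-positive means, which signal
    a corrupt or empty VOI.
    """
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError(f"cannot normalise course with non-positive mean ({m})")
    return x / m


def temporal_variance(series: BoldSeries, masks) -> float:
    """Sample SD (ddof=1) of the unity-mean-normalised VOI-mean course."""
    if series.n_frames < 2:
        raise ValueError("temporal variance needs at least 2 frames")
    course = normalize_unity_mean(volume_mean_course(series, masks))
    return float(np.std(course, ddof=1))


def voxel_paf(x: np.ndarray, convention: str = "mad") -> float:
    """Percent amplitude fluctuation of one voxel time course.

    ``mad``: 100 * mean|x - mu| / mu.  ``sd``: 100 * SD(x, ddof=1) / mu.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("voxel course needs at least 2 frames")
    mu = x.mean()
    if mu <= 0:
        raise ValueError(f"voxel course has non-positive mean ({mu})")
    if convention == "mad":
        return float(100.0 * np.abs(x - mu).mean() / mu)
    if convention == "sd":
        return float(100.0 * np.std(x, ddof=1) / mu)
    raise ValueError(f"unknown PAF convention {convention!r}; use one of {PAF_CONVENTIONS}")


def paf_map(series: BoldSeries, mask: VoiMask, convention: str = "mad"):
    """Per-voxel PAF over a VOI.

    Returns ``(values, n_excluded)`` where voxels with non-positive temporal
    mean are excluded from ``values`` and counted for QC.
    """
    if convention not in PAF_CONVENTIONS:
        raise ValueError(f"unknown PAF convention {convention!r}; use one of {PAF_CONVENTIONS}")
    vox = series.data[mask.data]  # (n_vox, t)
    mu = vox.mean(axis=1)
    valid = mu > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.warning("%d voxel(s) with non-positive mean excluded from PAF map", n_excluded)
    vox, mu = vox[valid], mu[valid]
    if convention == "mad":
        values = 100.0 * np.abs(vox - mu[:, None]).mean(axis=1) / mu
    else:
        values = 100.0 * np.std(vox, axis=1, ddof=1) / mu
    return values, n_excluded


def spatial_variance(series: BoldSeries, mask: VoiMask, convention: str = "mad") -> float:
    """Sample SD across voxels of mean-normalised per-voxel PAF."""
    values, _ = paf_map(series, mask, convention)
    if values.size < 2:
        raise ValueError("spatial variance needs at least 2 valid voxels")
    mean_paf = values.mean()
    if mean_paf < PAF_ZERO_TOL:
        log.warning("all-constant VOI: mean PAF is ~0, spatial variance defined as 0")
        return 0.0
    return float(np.std(values / mean_paf, ddof=1))


def compute_metrics(
    series: BoldSeries,
    mask: VoiMask,
    convention: str = "mad",
) -> VarianceMetrics:
    """TV and SV of one VOI in one series, with QC counts."""
    tv = temporal_variance(series, mask)
    values, n_excluded = paf_map(series, mask, convention)
    if values.size < 2:
        raise ValueError("spatial variance needs at least 2 valid voxels")
    mean_paf = values.mean()
    sv = 0.0 if mean_paf < PAF_ZERO_TOL else float(np.std(values / mean_paf, ddof=1))
    return VarianceMetrics(
        temporal_variance=tv,
        spatial_variance=sv,
        n_voxels=int(values.size),
        n_frames=series.n_frames,
        tissue=mask.label,
        n_excluded_voxels=n_excluded,
    )
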