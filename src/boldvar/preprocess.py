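"""VOI propagation, rigid slice-wise motion correction, and denoising.

Motion correction registers every axial slice of every frame to the matching
slice of a reference frame (frame 0 by default) under an in-plane rigid
transform, maximising normalized cross-correlation.  The search is a coarse
grid over translation and rotation followed by bounded 1D refinement of each
parameter; a translation-only fast path uses Fourier phase correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from ._geometry import resample_slice
from .types import BoldSeries, RigidTransform, VoiMask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationConfig:
    """Search bounds and resolution of the rigid registration."""

    max_shift: float = 5.0  # voxels, per axis
    max_angle: float = 10.0  # degrees
    shift_step: float = 1.0
    angle_step: float = 2.0
    shift_tol: float = 0.05  # refinement resolution, voxels
    angle_tol: float = 0.1  # refinement resolution, degrees
    refine_passes: int = 2  # coordinate-wise NCC refinement passes (0 = phase-corr only)


def propagate_voi(mask: VoiMask, n_frames: int) -> np.ndarray:
    """Copy the frame-0 VOI to every frame; returns a (x, y, z, t) bool stack."""
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    return np.repeat(mask.data[..., None], n_frames, axis=3)


def restrict_slices(mask: VoiMask, n_slices: int) -> VoiMask:
    """Keep the ``n_slices`` consecutive axial slices with the most VOI voxels.

    Ties break toward the lowest starting slice.  If the window is at least
    as deep as the grid the mask is returned unchanged (with a warning when
    it had to be clamped).
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    nz = mask.data.shape[2]
    if n_slices >= nz:
        if n_slices > nz:
            warnings.warn(f"n_slices={n_slices} exceeds grid depth {nz}; clamped", stacklevel=2)
        return VoiMask(mask.data.copy(), mask.label)
    per_slice = mask.data.sum(axis=(0, 1))
    window_counts = np.convolve(per_slice, np.ones(n_slices, dtype=int), mode="valid")
    start = int(np.argmax(window_counts))  # argmax takes the first maximum
    out = np.zeros_like(mask.data)
    out[:, :, start : start + n_slices] = mask.data[:, :, start : start + n_slices]
    return VoiMask(out, mask.label)


def ncc(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped images, in [-1, 1]."""
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {image_a.shape} vs {image_b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0:
        raise ValueError("image_a has zero intensity variance")
    if nb == 0:
        raise ValueError("image_b has zero intensity variance")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _ncc_at(ref: np.ndarray, moved: np.ndarray, dx: float, dy: float, theta: float) -> float:
    """NCC between the reference and the moved slice corrected by (dx,dy,theta)."""
    return ncc(ref, resample_slice(moved, dx, dy, theta, inverse=True))


def _register_slice(
    ref: np.ndarray, moved: np.ndarray, cfg: RegistrationConfig
) -> tuple[float, float, float]:
    """Estimate the forward rigid motion of ``moved`` relative to ``ref``."""
    thetas = (
        np.arange(-cfg.max_angle, cfg.max_angle + 1e-9, cfg.angle_step)
        if cfg.max_angle > 0
        else np.array([0.0])
    )
    best = (-np.inf, 0.0, 0.0, 0.0)
    for theta in thetas:
        unrotated = resample_slice(moved, 0.0, 0.0, theta, inverse=True)
        # Cross-correlation peak ("phase" normalization is unreliable after
        # bilinear resampling): the returned shift registers `unrotated` onto
        # `ref`, i.e. minus the forward translation.
        shift, _, _ = phase_cross_correlation(
            ref, unrotated, upsample_factor=20, normalization=None
        )
        dx = float(np.clip(-shift[0], -cfg.max_shift, cfg.max_shift))
        dy = float(np.clip(-shift[1], -cfg.max_shift, cfg.max_shift))
        score = _ncc_at(ref, moved, dx, dy, theta)
        if score > best[0]:
            best = (score, dx, dy, float(theta))
    _, dx, dy, theta = best

    # Bounded coordinate-wise refinement of the NCC objective, two passes.
    def refine(value, span, tol, objective):
        res = optimize.minimize_scalar(
            objective,
            bounds=(value - span, value + span),
            method="bounded",
            options={"xatol": tol},
        )
        return float(res.x)

    for _ in range(cfg.refine_passes):
        if cfg.max_angle > 0:
            theta = refine(
                theta, cfg.angle_step, cfg.angle_tol,
                lambda th: -_ncc_at(ref, moved, dx, dy, th),
            )
        dx = refine(dx, 1.0, cfg.shift_tol, lambda v: -_ncc_at(ref, moved, v, dy, theta))
        dy = refine(dy, 1.0, cfg.shift_tol, lambda v: -_ncc_at(ref, moved, dx, v, theta))
    return dx, dy, theta


def motion_correct(
    series: BoldSeries,
    reference_frame: int = 0,
    config: RegistrationConfig | None = None,
) -> tuple[BoldSeries, list[RigidTransform]]:
    """Slice-wise rigid motion correction against a reference frame.

    Returns the corrected series and the estimated forward transforms (one
    per non-reference frame and slice).  Each corrected slice is guaranteed
    an NCC against its reference at least as high as the uncorrected slice;
    otherwise the slice passes through unchanged with an identity transform.
    """
    cfg = config or RegistrationConfig()
    nt = series.n_frames
    if not (0 <= reference_frame < nt):
        raise ValueError(f"reference_frame {reference_frame} out of range [0, {nt})")
    nz = series.spatial_shape[2]
    out = series.data.copy()
    transforms: list[RigidTransform] = []
    for t in range(nt):
        if t == reference_frame:
            continue
        for z in range(nz):
            ref = series.data[:, :, z, reference_frame]
            moved = series.data[:, :, z, t]
            if ref.std() == 0 or moved.std() == 0:
                log.warning("frame %d slice %d has zero variance; identity transform", t, z)
                transforms.append(RigidTransform(t, z))
                continue
            dx, dy, theta = _register_slice(ref, moved, cfg)
            corrected = resample_slice(moved, dx, dy, theta, inverse=True)
            if ncc(ref, corrected) < ncc(ref, moved):  # non-worsening guarantee
                dx = dy = theta = 0.0
                corrected = moved
            out[:, :, z, t] = corrected
            transforms.append(RigidTransform(t, z, dx, dy, theta))
    return series.with_data(out), transforms


_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def denoise(
    series: BoldSeries,
    voi: VoiMask | None = None,
    fluid: VoiMask | None = None,
    filter_fwhm_frames: float = 3.0,
    regress_fluid: bool = True,
) -> BoldSeries:
    """Temporal low-pass filtering plus amniotic-fluid nuisance regression.

    Step 1: per-voxel Gaussian temporal smoothing (``filter_fwhm_frames <= 0``
    disables it).  Step 2: the unit-variance fluid-mean time course is
    regressed out of every voxel's demeaned course and the temporal mean is
    re-added, preserving intensity scale.  An empty/absent fluid mask skips
    step 2 with a warning.
    """
    if series.n_frames < 3:
        raise ValueError("denoise needs at least 3 frames")
    if voi is not None and fluid is not None and (voi.data & fluid.data).any():
        raise ValueError("VOI and fluid masks overlap")
    data = series.data
    if filter_fwhm_frames and filter_fwhm_frames > 0:
        sigma = filter_fwhm_frames * _FWHM_TO_SIGMA
        data = ndimage.gaussian_filter1d(data, sigma=sigma, axis=3, mode="nearest")
    if regress_fluid:
        if fluid is None or not fluid.data.any():
            log.warning("no fluid mask available; skipping nuisance regression")
        else:
            f = data[fluid.data].mean(axis=0)
            f = f - f.mean()
            f_sd = f.std(ddof=1)
            if f_sd == 0:
                log.warning("fluid course is constant; skipping nuisance regression")
            else:
                f = f / f_sd
                flat = data.reshape(-1, series.n_frames)
                means = flat.mean(axis=1, keepdims=True)
                centered = flat - means
                beta = centered @ f / (f @ f)
                data = (centered - np.outer(beta, f) + means).reshape(data.shape)
    return series.with_data(data)


def frame_ncc_score(series: BoldSeries) -> float:
    """Mean NCC between matching slices of consecutive frames (QC score).

    Higher means less apparent frame-to-frame motion.  Zero-variance slices
    are skipped.
    """
    nz = series.spatial_shape[2]
    scores = []
    for t in range(series.n_frames - 1):
        for z in range(nz):
            a = series.data[:, :, z, t]
            b = series.data[:, :, z, t + 1]
            if a.std() == 0 or b.std() == 0:
                continue
            scores.append(ncc(a, b))
    if not scores:
        raise ValueError("no slice pair with nonzero variance")
    return float(np.mean(scores))
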