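"""Synthetic 4D BOLD phantoms and covariate cohorts with known ground truth.

The phantom emulates the signal structure the analysis pipeline is built to
measure: a cyclical inflow component riding on a stationary baseline, patchwise
amplitude heterogeneity across cotyledon-like regions, an independently
fluctuating amniotic-fluid compartment, frame-to-frame rigid slice motion, and
additive Gaussian noise.  The cohort generator produces covariate tables with
a known linear dependence of the variance metrics on gestational age, maternal
risk factors and CHD status, with optionally heteroskedastic residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._geometry import resample_slice
from .errors import SpecValidationError
from .types import BoldSeries, RigidTransform, VoiMask, transforms_as_array

# Baseline contrast between compartments: gives slices enough spatial structure
# for intensity-based registration to have a well-defined optimum.
_TISSUE_BASELINE_FACTOR = {"placenta": 1.0, "fluid": 1.3, "brain": 0.8, "background": 0.2}
_PATCH_BASELINE_JITTER = 0.10  # fractional baseline modulation per cotyledon patch


@dataclass
class PhantomSpec:
    """Parameters of one synthetic 4D BOLD acquisition."""

    grid_shape: tuple[int, int, int, int] = (16, 16, 5, 50)
    tr_seconds: float = 2.28
    baseline_intensity: float = 100.0
    inflow_amplitude: float = 0.05
    inflow_period_s: float = 45.6  # 20 frames at the default TR
    n_patches: int = 0
    patch_amplitude_spread: float = 0.0
    noise_sd: float = 0.0
    motion_max_voxels: float = 0.0
    motion_max_degrees: float = 0.0
    fluid_fraction: float = 0.0
    brain_amplitude: float | None = None
    brain_amplitude_spread: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        gs = self.grid_shape
        if len(gs) != 4 or any(int(v) != v or v < 1 for v in gs):
            raise SpecValidationError(f"grid_shape must be 4 positive integers, got {gs}")
        if gs[3] < 2:
            raise SpecValidationError(f"grid_shape: need t >= 2 frames, got {gs[3]}")
        for name in ("tr_seconds", "baseline_intensity", "inflow_period_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise SpecValidationError(f"{name} must be a positive finite real, got {v}")
        for name in (
            "inflow_amplitude",
            "patch_amplitude_spread",
            "noise_sd",
            "motion_max_voxels",
            "motion_max_degrees",
            "brain_amplitude_spread",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SpecValidationError(f"{name} must be a nonnegative finite real, got {v}")
        if self.inflow_amplitude >= 1:
            raise SpecValidationError(
                f"inflow_amplitude must be < 1 to keep intensities positive, "
                f"got {self.inflow_amplitude}"
            )
        if not (0 <= self.fluid_fraction < 1):
            raise SpecValidationError(f"fluid_fraction must be in [0, 1), got {self.fluid_fraction}")
        if self.brain_amplitude is not None and not (0 <= self.brain_amplitude < 1):
            raise SpecValidationError(f"brain_amplitude must be in [0, 1), got {self.brain_amplitude}")
        if int(self.n_patches) != self.n_patches or self.n_patches < 0:
            raise SpecValidationError(f"n_patches must be a nonnegative integer, got {self.n_patches}")


@dataclass
class GroundTruth:
    """Analytic quantities of the noise-free, motion-free phantom signal."""

    true_transforms: np.ndarray  # (t, z, 3): dx, dy voxels; theta degrees
    true_patch_amplitudes: np.ndarray  # per-patch fractional inflow amplitude
    true_tv: float  # placental temporal variance of the clean signal
    true_sv: float  # placental spatial variance of the clean signal
    per_tissue: dict = field(default_factory=dict)  # tissue -> {"tv": .., "sv": ..}

    def __post_init__(self) -> None:
        if self.true_tv < 0 or self.true_sv < 0:
            raise ValueError("ground-truth variances must be nonnegative")

    def as_dict(self) -> dict:
        return {
            "true_tv": self.true_tv,
            "true_sv": self.true_sv,
            "true_patch_amplitudes": self.true_patch_amplitudes.tolist(),
            "per_tissue": self.per_tissue,
        }


@dataclass
class CohortSpec:
    """Parameters of a synthetic covariate cohort with known effect sizes.

    The structural model for every metric column is
    ``metric = beta0 + beta_ga*GA + beta_mrf*any_mrf + beta_chd*CHD
    + beta_interaction*any_mrf*CHD + eps`` with ``eps`` zero-mean Gaussian
    whose SD scales with ``1 + hetero_scale * standardized(GA)``.
    """

    n_subjects: int = 60
    ga_range_weeks: tuple[float, float] = (27.0, 40.0)
    prev_obesity: float = 0.3
    prev_hypertension: float = 0.25
    prev_diabetes: float = 0.2
    prev_chd: float = 0.5
    beta0: float = 5.0
    beta_ga: float = 0.0
    beta_mrf: float = 0.0
    beta_chd: float = 0.0
    beta_interaction: float = 0.0
    noise_sd: float = 0.1
    hetero_scale: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_subjects) != self.n_subjects or self.n_subjects < 4:
            raise SpecValidationError(f"n_subjects must be an integer >= 4, got {self.n_subjects}")
        lo, hi = self.ga_range_weeks
        if not (27 <= lo <= hi <= 42):
            raise SpecValidationError(
                f"ga_range_weeks must satisfy 27 <= low <= high <= 42, got {self.ga_range_weeks}"
            )
        for name in ("prev_obesity", "prev_hypertension", "prev_diabetes", "prev_chd"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SpecValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta0", "beta_ga", "beta_mrf", "beta_chd", "beta_interaction"):
            if not np.isfinite(getattr(self, name)):
                raise SpecValidationError(f"{name} must be finite")
        for name in ("noise_sd", "hetero_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SpecValidationError(f"{name} must be a nonnegative finite real, got {v}")


def default_masks(spatial_shape: tuple[int, int, int]) -> dict[str, VoiMask]:
    """Disjoint placenta / fluid / brain compartments along the x axis.

    On grids with x >= 8 the compartments are separated by one-voxel
    background gaps so that sub-voxel resampling cannot bleed signal from one
    compartment into another's mask.
    """
    nx, ny, nz = spatial_shape
    gap = 1 if nx >= 8 else 0
    x_plac = max(1, round(0.42 * nx))
    x_fluid = max(1, round(0.15 * nx))
    if x_plac + x_fluid + 2 * gap >= nx:  # tiny grids: keep one x-plane for brain
        x_plac, x_fluid, gap = max(1, nx - 2), 1 if nx >= 3 else 0, 0
    masks = {}
    full = np.zeros((nx, ny, nz), dtype=bool)
    plac = full.copy()
    plac[:x_plac] = True
    masks["placenta"] = VoiMask(plac, "placenta")
    fluid_lo = x_plac + gap
    if x_fluid > 0 and fluid_lo + x_fluid + gap < nx:
        fluid = full.copy()
        fluid[fluid_lo : fluid_lo + x_fluid] = True
        masks["fluid"] = VoiMask(fluid, "fluid")
        brain_lo = fluid_lo + x_fluid + gap
    else:
        brain_lo = x_plac + gap
    brain = full.copy()
    brain[brain_lo:] = True
    masks["brain"] = VoiMask(brain, "brain")
    return masks


def _voronoi_patches(mask: np.ndarray, n_patches: int, rng: np.random.Generator) -> np.ndarray:
    """Label in-mask voxels by nearest of ``n_patches`` randomly placed seeds."""
    coords = np.argwhere(mask)  # (n_vox, 3)
    labels = np.full(mask.shape, -1, dtype=int)
    if n_patches <= 1:
        labels[mask] = 0
        return labels
    idx = rng.choice(len(coords), size=min(n_patches, len(coords)), replace=False)
    seeds = coords[idx].astype(float)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels[mask] = np.argmin(d2, axis=1)
    return labels


def _normalized_course_sd(course: np.ndarray) -> float:
    m = course.mean()
    return float(np.std(course / m, ddof=1))


def _clean_tv_sv(clean: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """TV and SV of a noise-free 4D signal restricted to ``mask``."""
    vox = clean[mask]  # (n_vox, t)
    tv = _normalized_course_sd(vox.mean(axis=0))
    mu = vox.mean(axis=1, keepdims=True)
    paf = 100.0 * np.abs(vox - mu).mean(axis=1) / mu[:, 0]
    mean_paf = paf.mean()
    # below ~1e-10 percent the "fluctuation" is float rounding of a constant course
    sv = 0.0 if mean_paf < 1e-10 else float(np.std(paf / mean_paf, ddof=1))
    return tv, sv


def generate_bold_phantom(
    spec: PhantomSpec,
) -> tuple[BoldSeries, dict[str, VoiMask], GroundTruth]:
    """Generate a 4D phantom, its tissue masks, and analytic ground truth.

    Voxel model (placenta and brain): ``baseline_v * (1 + a_v * sin(2*pi*t_n /
    period)) + noise`` where ``a_v`` is the cotyledon-patch amplitude of the
    voxel.  The amniotic-fluid compartment follows an independent slower
    sinusoid of fractional amplitude ``fluid_fraction``.  Ground truth is
    computed from the clean signal before motion and noise are applied.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz, nt = (int(v) for v in spec.grid_shape)
    masks = default_masks((nx, ny, nz))
    plac = masks["placenta"].data
    brain = masks["brain"].data
    fluid = masks["fluid"].data if "fluid" in masks else np.zeros_like(plac)

    # --- amplitude field -------------------------------------------------
    amp = np.zeros((nx, ny, nz))
    labels = _voronoi_patches(plac, spec.n_patches, rng)
    n_eff = max(1, min(spec.n_patches, int(plac.sum()))) if spec.n_patches else 1
    patch_amps = spec.inflow_amplitude * (
        1.0 + spec.patch_amplitude_spread * rng.standard_normal(n_eff)
    )
    patch_amps = np.clip(patch_amps, 0.0, 0.95)
    amp[plac] = patch_amps[labels[plac]]
    brain_a = 0.5 * spec.inflow_amplitude if spec.brain_amplitude is None else spec.brain_amplitude
    amp[brain] = np.clip(
        brain_a * (1.0 + spec.brain_amplitude_spread * rng.standard_normal(int(brain.sum()))),
        0.0,
        0.95,
    )

    # --- baseline field with deterministic texture and patch jitter ------
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    texture = 1.0 + 0.1 * np.sin(2 * np.pi * xg / nx) * np.cos(2 * np.pi * yg / ny)
    base = np.full((nx, ny, nz), _TISSUE_BASELINE_FACTOR["background"])
    base[plac] = _TISSUE_BASELINE_FACTOR["placenta"]
    base[fluid] = _TISSUE_BASELINE_FACTOR["fluid"]
    base[brain] = _TISSUE_BASELINE_FACTOR["brain"]
    if spec.n_patches > 1:
        jitter = 1.0 + _PATCH_BASELINE_JITTER * rng.uniform(-1, 1, size=n_eff)
        base[plac] *= jitter[labels[plac]]
    base = spec.baseline_intensity * base * texture[:, :, None]

    # --- clean 4D signal -------------------------------------------------
    times = np.arange(nt) * spec.tr_seconds
    s = np.sin(2 * np.pi * times / spec.inflow_period_s)
    clean = base[..., None] * (1.0 + amp[..., None] * s)
    if fluid.any():
        s_fluid = np.sin(2 * np.pi * times / (2.7 * spec.inflow_period_s) + 1.3)
        clean[fluid] = base[fluid][:, None] * (1.0 + spec.fluid_fraction * s_fluid)

    tv_p, sv_p = _clean_tv_sv(clean, plac)
    tv_b, sv_b = _clean_tv_sv(clean, brain)
    per_tissue = {
        "placenta": {"tv": tv_p, "sv": sv_p},
        "brain": {"tv": tv_b, "sv": sv_b},
    }

    # --- motion and noise ------------------------------------------------
    transforms = np.zeros((nt, nz, 3))
    if spec.motion_max_voxels > 0 or spec.motion_max_degrees > 0:
        transforms[1:, :, 0] = rng.uniform(-spec.motion_max_voxels, spec.motion_max_voxels, (nt - 1, nz))
        transforms[1:, :, 1] = rng.uniform(-spec.motion_max_voxels, spec.motion_max_voxels, (nt - 1, nz))
        transforms[1:, :, 2] = rng.uniform(-spec.motion_max_degrees, spec.motion_max_degrees, (nt - 1, nz))

    series = BoldSeries(clean, tr_seconds=spec.tr_seconds)
    if transforms.any():
        series = apply_motion(series, transforms)
    if spec.noise_sd > 0:
        series = series.with_data(series.data + rng.normal(0.0, spec.noise_sd, series.data.shape))

    truth = GroundTruth(
        true_transforms=transforms,
        true_patch_amplitudes=np.asarray(patch_amps),
        true_tv=tv_p,
        true_sv=sv_p,
        per_tissue=per_tissue,
    )
    return series, masks, truth


def apply_motion(
    series: BoldSeries,
    transforms: Sequence[Sequence[RigidTransform]] | np.ndarray,
) -> BoldSeries:
    """Corrupt a series with per-frame, per-slice rigid motion.

    Frame 0 is the registration reference and is left untouched by
    convention.  Slices are resampled with bilinear interpolation.
    """
    nt = series.n_frames
    nz = series.spatial_shape[2]
    arr = transforms_as_array(transforms, nt, nz)
    max_extent = max(series.spatial_shape[:2])
    if np.abs(arr[:, :, :2]).max() > max_extent:
        raise ValueError("translation exceeds grid extent")
    out = series.data.copy()
    for t in range(1, nt):
        for z in range(nz):
            dx, dy, theta = arr[t, z]
            if dx or dy or theta:
                out[:, :, z, t] = resample_slice(series.data[:, :, z, t], dx, dy, theta)
    return series.with_data(out)


_METRIC_COLUMNS = ("tv_placenta", "sv_placenta", "tv_brain", "sv_brain")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a covariate table with metrics following a known linear model.

    Returns one row per subject with columns ``subject_id, ga_weeks, chd,
    obesity, hypertension, diabetes, any_mrf`` and the four metric columns
    ``tv_placenta, sv_placenta, tv_brain, sv_brain`` (independent noise per
    column, identical structural coefficients).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_subjects)
    ga = rng.uniform(*spec.ga_range_weeks, size=n)
    obesity = (rng.random(n) < spec.prev_obesity).astype(int)
    hypertension = (rng.random(n) < spec.prev_hypertension).astype(int)
    diabetes = (rng.random(n) < spec.prev_diabetes).astype(int)
    chd = (rng.random(n) < spec.prev_chd).astype(int)
    any_mrf = np.maximum.reduce([obesity, hypertension, diabetes])

    ga_sd = ga.std()
    z_ga = (ga - ga.mean()) / ga_sd if ga_sd > 0 else np.zeros(n)
    resid_sd = spec.noise_sd * np.maximum(0.1, 1.0 + spec.hetero_scale * z_ga)
    mean = (
        spec.beta0
        + spec.beta_ga * ga
        + spec.beta_mrf * any_mrf
        + spec.beta_chd * chd
        + spec.beta_interaction * any_mrf * chd
    )
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "ga_weeks": ga,
            "chd": chd,
            "obesity": obesity,
            "hypertension": hypertension,
            "diabetes": diabetes,
            "any_mrf": any_mrf,
        }
    )
    for col in _METRIC_COLUMNS:
        df[col] = mean + resid_sd * rng.standard_normal(n)
    return df
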