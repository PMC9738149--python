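"""End-to-end orchestration: simulate -> preprocess -> metrics -> stats.

A single :class:`RunConfig` (constructible from a YAML mapping) drives the
whole run.  All randomness flows from one integer seed; per-subject phantom
seeds are spawned deterministically from it, so re-running a config
reproduces every output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .errors import SpecValidationError
from .metrics import compute_metrics
from .preprocess import RegistrationConfig, denoise, frame_ncc_score, motion_correct
from .stats import group_comparisons, run_battery
from .synthdata import CohortSpec, PhantomSpec, generate_bold_phantom, generate_cohort
from .types import BoldSeries

log = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class PreprocessOptions:
    motion_correct: bool = True
    max_shift: float = 5.0
    max_angle: float = 0.0  # translation-only by default for synthetic runs
    refine_passes: int = 0  # phase-correlation subpixel estimate is enough here
    filter_fwhm_frames: float = 3.0
    regress_fluid: bool = True


@dataclass
class StatsOptions:
    n_boot: int = 2000
    direction: str = "less"
    n_permutations: int = 2000
    group_comparisons: bool = True


@dataclass
class SyntheticOptions:
    """Cohort-level effect structure plus the per-subject phantom template.

    Cohort metric columns are interpreted on a percent scale: a target
    ``tv_placenta`` of 5.0 means a 5% temporal fluctuation, realised in the
    phantom by setting the inflow amplitude so the analytic TV of the clean
    signal is 0.05.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "boldvar_run"
    synthetic: SyntheticOptions | None = None
    bold_paths: list[str] | None = None  # real-data mode: one NIfTI per subject
    mask_paths: dict[str, list[str]] | None = None  # label -> per-subject NIfTI
    covariates_csv: str | None = None
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)

    def validate(self) -> None:
        synthetic = self.synthetic is not None
        real = self.bold_paths is not None
        if synthetic == real:
            raise SpecValidationError(
                "config must set exactly one of 'synthetic' or 'bold_paths'"
            )
        if real:
            missing = [p for p in self.bold_paths if not Path(p).exists()]
            for label, paths in (self.mask_paths or {}).items():
                missing += [p for p in paths if not Path(p).exists()]
            if self.covariates_csv and not Path(self.covariates_csv).exists():
                missing.append(self.covariates_csv)
            if missing:
                raise SpecValidationError(f"missing input file(s): {missing}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            s = dict(d["synthetic"])
            s["cohort"] = CohortSpec(**s.get("cohort", {}))
            s["phantom"] = PhantomSpec(**{
                **s.get("phantom", {}),
                "grid_shape": tuple(s.get("phantom", {}).get("grid_shape", (16, 16, 5, 50))),
            })
            d["synthetic"] = SyntheticOptions(**s)
        if "preprocess" in d:
            d["preprocess"] = PreprocessOptions(**d["preprocess"])
        if "stats" in d:
            d["stats"] = StatsOptions(**d["stats"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def select_series(series_list: list[BoldSeries]) -> int:
    """Index of the candidate series with the least apparent motion.

    Quantitative proxy for a visual least-motion call: highest mean
    frame-to-frame NCC wins; ties break toward the lowest index.
    """
    if not series_list:
        raise ValueError("no candidate series")
    scores = np.array([frame_ncc_score(s) for s in series_list])
    return int(np.argmax(scores))


def _phantom_for_subject(template: PhantomSpec, row: pd.Series, seed: int) -> PhantomSpec:
    """Instantiate the phantom template with this subject's target metrics."""
    nt = template.grid_shape[3]
    times = np.arange(nt) * template.tr_seconds
    s = np.sin(2 * np.pi * times / template.inflow_period_s)
    sd_s = float(np.std(s, ddof=1))
    amp = max(1e-4, (row["tv_placenta"] / 100.0) / sd_s)
    brain_amp = max(1e-4, (row["tv_brain"] / 100.0) / sd_s)
    spec = PhantomSpec(**{**asdict(template), "grid_shape": tuple(template.grid_shape)})
    spec.inflow_amplitude = min(amp, 0.95)
    spec.brain_amplitude = min(brain_amp, 0.95)
    spec.patch_amplitude_spread = max(0.0, row["sv_placenta"] / 100.0)
    spec.brain_amplitude_spread = max(0.0, row["sv_brain"] / 100.0)
    spec.n_patches = max(int(template.n_patches), 4)
    spec.seed = seed
    return spec


def run(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the configured pipeline; returns the results bundle.

    Bundle keys: ``cohort`` (target covariate table, synthetic mode),
    ``metrics`` (measured per-subject metrics), ``stats`` (regression
    battery), ``comparisons`` (group-comparison JSON-able dict), ``qc``.
    Outputs are written under ``config.output_dir`` unless disabled.
    """
    config.validate()
    if config.synthetic is None:
        raise NotImplementedError(
            "real-data mode requires per-subject masks and covariates; "
            "use the stage CLIs (preprocess/metrics/stats) for real inputs"
        )
    t0 = time.time()
    out_dir = Path(config.output_dir)
    cohort = generate_cohort(_with_seed(config.synthetic.cohort, config.seed))
    seeds = np.random.SeedSequence(config.seed).spawn(len(cohort))

    qc: dict = {"subjects": {}, "n_input": len(cohort), "n_dropped": 0, "n_analyzed": 0}
    measured_rows = []
    reg_cfg = RegistrationConfig(
        max_shift=config.preprocess.max_shift,
        max_angle=config.preprocess.max_angle,
        refine_passes=config.preprocess.refine_passes,
    )
    for (_, row), ss in zip(cohort.iterrows(), seeds):
        sid = row["subject_id"]
        try:
            spec = _phantom_for_subject(
                config.synthetic.phantom, row, int(ss.generate_state(1)[0] % (2**31))
            )
            series, masks, _ = generate_bold_phantom(spec)
            subject_qc = {"frames": series.n_frames, "ncc_before": frame_ncc_score(series)}
            if config.preprocess.motion_correct:
                series, _ = motion_correct(series, reference_frame=0, config=reg_cfg)
            subject_qc["ncc_after"] = frame_ncc_score(series)
            series = denoise(
                series,
                voi=masks["placenta"],
                fluid=masks.get("fluid"),
                filter_fwhm_frames=config.preprocess.filter_fwhm_frames,
                regress_fluid=config.preprocess.regress_fluid,
            )
            rec = {"subject_id": sid}
            excluded = 0
            for tissue in ("placenta", "brain"):
                m = compute_metrics(series, masks[tissue])
                rec[f"tv_{tissue}"] = 100.0 * m.temporal_variance
                rec[f"sv_{tissue}"] = 100.0 * m.spatial_variance
                excluded += m.n_excluded_voxels
            subject_qc["excluded_voxels"] = excluded
            measured_rows.append(rec)
            qc["subjects"][sid] = subject_qc
            qc["n_analyzed"] += 1
        except (ValueError, SpecValidationError) as exc:
            log.warning("subject %s dropped: %s", sid, exc)
            qc["subjects"][sid] = {"dropped": str(exc)}
            qc["n_dropped"] += 1

    measured = pd.DataFrame(measured_rows)
    analysis = cohort.drop(columns=[c for c in cohort.columns if c.startswith(("tv_", "sv_"))])
    analysis = analysis.merge(measured, on="subject_id", how="inner")

    battery = run_battery(
        analysis,
        n_boot=config.stats.n_boot,
        seed=config.seed,
        direction=config.stats.direction,
    )
    comparisons = (
        group_comparisons(
            analysis, seed=config.seed, n_permutations=config.stats.n_permutations
        )
        if config.stats.group_comparisons and analysis["chd"].nunique() > 1
        else {}
    )
    qc["runtime_s"] = round(time.time() - t0, 3)
    qc["config_hash"] = config.config_hash()
    qc["seed"] = config.seed

    bundle = {
        "cohort": cohort,
        "metrics": analysis,
        "stats": battery,
        "comparisons": comparisons,
        "qc": qc,
    }
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort_targets.csv", index=False)
        analysis.to_csv(out_dir / "metrics.csv", index=False)
        battery.to_csv(out_dir / "stats.csv", index=False)
        bio.save_json(comparisons, out_dir / "comparisons.json")
        bio.save_json(qc, out_dir / "qc.json")
    return bundle


def _with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    d = asdict(spec)
    d["seed"] = seed
    d["ga_range_weeks"] = tuple(d["ga_range_weeks"])
    return CohortSpec(**d)
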