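"""Regression and group-comparison battery for the variance metrics.

Main inference engine: heteroskedasticity-robust one-sided inference on a
maternal-risk-factor coefficient via a null-restricted wild bootstrap with
Rademacher multipliers, adjusted for gestational age, optionally with a CHD
interaction; Benjamini–Hochberg FDR across the predictor family.  Group
comparisons: GA-adjusted two-sample Kolmogorov–Smirnov, histogram-moment
tests (variance-ratio F; permutation for skewness/kurtosis), and Welch t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError

log = logging.getLogger(__name__)

MRF_PREDICTORS = ("any_mrf", "diabetes", "hypertension", "obesity")


@dataclass
class DesignMatrix:
    columns: list[str]
    values: np.ndarray  # (n, k)
    target_column: str

    @property
    def target_index(self) -> int:
        return self.columns.index(self.target_column)

    def validate(self) -> None:
        n, k = self.values.shape
        if len(self.columns) != k:
            raise ValueError("column names do not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateDesignError("design matrix contains non-finite values")
        if np.linalg.matrix_rank(self.values) < k:
            raise DegenerateDesignError(
                f"design matrix is rank deficient (k={k}, columns={self.columns})"
            )


@dataclass(frozen=True)
class RegressionResult:
    coefficient: float
    p_one_sided: float
    p_fdr: float
    n_boot: int
    n_obs: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_one_sided <= 1):
            raise ValueError("p_one_sided outside [0, 1]")
        if not (np.isnan(self.p_fdr) or 0 <= self.p_fdr <= 1):
            raise ValueError("p_fdr outside [0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def build_design(
    records: pd.DataFrame,
    predictor: str,
    include_interaction: bool = False,
    ga_column: str = "ga_weeks",
    chd_column: str = "chd",
) -> DesignMatrix:
    """Design [1, GA, predictor(, CHD, predictor*CHD)] with the tested column marked.

    For main-effect tests the target is the predictor; with the interaction
    the target is the product column.
    """
    pred = np.asarray(records[predictor], dtype=float)
    ga = np.asarray(records[ga_column], dtype=float)
    n = len(records)
    if np.all(pred == pred[0]):
        raise DegenerateDesignError(f"predictor {predictor!r} is constant across records")
    if include_interaction:
        chd = np.asarray(records[chd_column], dtype=float)
        values = np.column_stack([np.ones(n), ga, pred, chd, pred * chd])
        columns = ["intercept", ga_column, predictor, chd_column, f"{predictor}:{chd_column}"]
        target = f"{predictor}:{chd_column}"
    else:
        values = np.column_stack([np.ones(n), ga, pred])
        columns = ["intercept", ga_column, predictor]
        target = predictor
    if n < values.shape[1] + 2:
        raise DegenerateDesignError(f"too few records ({n}) for a {values.shape[1]}-column design")
    design = DesignMatrix(columns=columns, values=values, target_column=target)
    design.validate()
    return design


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares via QR; returns (coefficients, residuals, fitted)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y length does not match design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return beta, y - fitted, fitted


def wild_bootstrap_p(
    design: DesignMatrix,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    direction: str = "less",
) -> RegressionResult:
    """One-sided wild-bootstrap p-value for the design's target coefficient.

    The null model (target coefficient forced to 0) is fit, and bootstrap
    responses ``y* = fitted_null + r_null * v`` are formed with i.i.d.
    Rademacher multipliers ``v`` per observation.  The full model is refit on
    each replicate; ``p = (1 + #extreme) / (n_boot + 1)`` where "extreme"
    means the replicate coefficient is <= (direction "less") or >= ("greater")
    the observed one.  Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    design.validate()
    X = design.values
    y = np.asarray(y, dtype=float)
    j = design.target_index
    beta_hat = ols_fit(X, y)[0][j]

    X_null = np.delete(X, j, axis=1)
    _, r_null, fitted_null = ols_fit(X_null, y)

    rng = np.random.default_rng(seed)
    v = rng.integers(0, 2, size=(y.shape[0], n_boot)) * 2 - 1
    y_star = fitted_null[:, None] + r_null[:, None] * v
    pinv = np.linalg.pinv(X)
    beta_star = (pinv @ y_star)[j]
    if direction == "less":
        extreme = int(np.sum(beta_star <= beta_hat))
    else:
        extreme = int(np.sum(beta_star >= beta_hat))
    p = (1 + extreme) / (n_boot + 1)
    return RegressionResult(
        coefficient=float(beta_hat),
        p_one_sided=float(p),
        p_fdr=float("nan"),
        n_boot=n_boot,
        n_obs=int(y.shape[0]),
        seed=seed,
    )


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def ga_adjust(values: np.ndarray, ga: np.ndarray) -> np.ndarray:
    """Residuals of a single pooled least-squares fit of values on [1, GA]."""
    values = np.asarray(values, dtype=float)
    ga = np.asarray(ga, dtype=float)
    if values.shape != ga.shape or values.ndim != 1:
        raise ValueError("values and ga must be 1D vectors of equal length")
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(ga == ga[0]):
        log.warning("constant GA: returning mean-centered values")
        return values - values.mean()
    X = np.column_stack([np.ones_like(ga), ga])
    _, resid, _ = ols_fit(X, values)
    return resid


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D and asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError(f"each group needs >= 5 observations (got {a.size}, {b.size})")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def moment_compare(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Compare variance (F-test) and skewness/kurtosis (permutation) of two samples.

    Variance uses the two-sided variance-ratio F-test.  Skewness and excess
    kurtosis differences are tested by a seeded permutation of group labels.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 8 or b.size < 8:
        raise ValueError(f"each group needs >= 8 observations (got {a.size}, {b.size})")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in one of the groups")
    F = va / vb
    fdist = sps.f(a.size - 1, b.size - 1)
    p_var = 2.0 * min(fdist.cdf(F), fdist.sf(F))
    p_var = min(1.0, p_var)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = a.size
    out: dict[str, tuple[float, float]] = {"variance": (float(F), float(p_var))}
    for name, fn in (("skewness", sps.skew), ("kurtosis", sps.kurtosis)):
        observed = fn(a) - fn(b)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            stat = fn(perm[:na]) - fn(perm[na:])
            if abs(stat) >= abs(observed):
                count += 1
        p = (1 + count) / (n_permutations + 1)
        out[name] = (float(observed), float(p))
    return out


def welch_t(a, b) -> tuple[float, float]:
    """Welch unequal-variance t-test from raw samples or (mean, sd, n) triples."""

    def summarise(x):
        if isinstance(x, tuple) and len(x) == 3:
            mean, sd, n = x
        else:
            x = np.asarray(x, dtype=float)
            mean, sd, n = x.mean(), x.std(ddof=1), x.size
        if n < 2:
            raise ValueError(f"need n >= 2 per group, got {n}")
        if sd <= 0:
            raise ValueError("group SD must be positive")
        return float(mean), float(sd), int(n)

    m1, s1, n1 = summarise(a)
    m2, s2, n2 = summarise(b)
    se1, se2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * sps.t(df).sf(abs(t))
    return float(t), float(p)


def run_battery(
    records: pd.DataFrame,
    metric_columns: list[str] | None = None,
    predictors: tuple[str, ...] = MRF_PREDICTORS,
    effect_types: tuple[str, ...] = ("main", "interaction"),
    n_boot: int = 5000,
    seed: int = 0,
    direction: str = "less",
) -> pd.DataFrame:
    """Wild-bootstrap regressions for every (metric, predictor, effect) cell.

    FDR adjustment is applied within each (tissue, metric, effect-type)
    family across the predictor set.  Degenerate designs (e.g. a flag with
    zero prevalence) yield a row with status ``degenerate_design`` and NaN
    statistics instead of a number.
    """
    if metric_columns is None:
        metric_columns = [c for c in records.columns if c.startswith(("tv_", "sv_"))]
    rows = []
    for col in metric_columns:
        metric, _, tissue = col.partition("_")
        y = np.asarray(records[col], dtype=float)
        for effect in effect_types:
            cell_seed = seed
            block = []
            for predictor in predictors:
                row = {
                    "tissue": tissue,
                    "metric": metric,
                    "predictor": predictor,
                    "effect_type": effect,
                    "coefficient": np.nan,
                    "p_one_sided": np.nan,
                    "p_fdr": np.nan,
                    "n_boot": n_boot,
                    "seed": cell_seed,
                    "status": "ok",
                }
                try:
                    design = build_design(records, predictor, include_interaction=effect == "interaction")
                    res = wild_bootstrap_p(design, y, n_boot=n_boot, seed=cell_seed, direction=direction)
                    row["coefficient"] = res.coefficient
                    row["p_one_sided"] = res.p_one_sided
                    row["n_obs"] = res.n_obs
                except DegenerateDesignError as exc:
                    row["status"] = "degenerate_design"
                    log.warning("degenerate design for %s/%s/%s: %s", col, predictor, effect, exc)
                block.append(row)
                cell_seed += 1
            ok = [r for r in block if r["status"] == "ok"]
            if ok:
                adjusted = fdr_adjust(np.array([r["p_one_sided"] for r in ok]))
                for r, p_adj in zip(ok, adjusted):
                    r["p_fdr"] = p_adj
            rows.extend(block)
    return pd.DataFrame(rows)


def group_comparisons(
    records: pd.DataFrame,
    metric_columns: list[str] | None = None,
    group_column: str = "chd",
    seed: int = 0,
    n_permutations: int = 2000,
) -> dict:
    """GA-adjusted K-S plus histogram-moment comparisons between two groups."""
    if metric_columns is None:
        metric_columns = [c for c in records.columns if c.startswith(("tv_", "sv_"))]
    grp = np.asarray(records[group_column], dtype=int)
    ga = np.asarray(records["ga_weeks"], dtype=float)
    out: dict = {}
    for col in metric_columns:
        values = np.asarray(records[col], dtype=float)
        resid = ga_adjust(values, ga)
        a, b = resid[grp == 1], resid[grp == 0]
        entry: dict = {"n_group": int(a.size), "n_reference": int(b.size)}
        try:
            D, p = ks_two_sample(a, b)
            entry["ks"] = {"D": D, "p": p}
            entry["moments"] = {
                k: {"stat": s, "p": p_}
                for k, (s, p_) in moment_compare(a, b, n_permutations=n_permutations, seed=seed).items()
            }
            t, p_t = welch_t(a, b)
            entry["welch_t"] = {"t": t, "p": p_t}
        except ValueError as exc:
            entry["status"] = f"skipped: {exc}"
        out[col] = entry
    return out
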