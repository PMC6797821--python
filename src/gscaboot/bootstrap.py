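"""Nonparametric bootstrap and jackknife confidence intervals.

Implements the three interval constructions compared in the coverage/balance
study, for every free GSCA parameter:

* percentile — the interval between the round(B*alpha/2)-th and
  round(B*(1-alpha/2))-th order statistics of the bootstrap replicates
  (1-based, clamped to [1, B]);
* BCa — percentile-type interval whose quantile levels are adjusted by a
  bias-correction factor ``z0`` (median bias of the replicates) and an
  acceleration factor ``a`` estimated by leave-one-out jackknife;
* Student's t — ``estimate +/- t_{n-1}(1-alpha/2) * se`` with the bootstrap
  standard error.

Every bootstrap or jackknife refit re-runs the full estimation pipeline
(column re-standardization included) and is sign-aligned to the original
solution so that the replicate distribution is free of component sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gsca import (
    GSCAResult,
    InadmissibleSampleError,
    _as_matrix,
    _compiled,
    _fit_from_standardized,
    sign_align,
    standardize,
)
from .model import ModelSpec

__all__ = [
    "BootstrapDistribution",
    "JackknifeDistribution",
    "ConfidenceInterval",
    "resample_indices",
    "bootstrap_distribution",
    "jackknife_distribution",
    "bootstrap_statistic",
    "jackknife_statistic",
    "bootstrap_se",
    "critical_ratio",
    "percentile_ci",
    "bias_correction",
    "acceleration",
    "bca_ci",
    "student_t_ci",
    "confidence_intervals",
]


@dataclass
class BootstrapDistribution:
    """B aligned re-estimates of every parameter plus the original estimates."""

    estimates: pd.DataFrame  # B x K
    original: pd.Series  # K
    n: int  # original sample size
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not np.all(np.isfinite(self.estimates.to_numpy())):
            raise ValueError("non-finite bootstrap replicate")
        if list(self.estimates.columns) != list(self.original.index):
            raise ValueError("replicate labels do not match the original estimates")

    @property
    def B(self) -> int:
        return len(self.estimates)


@dataclass
class JackknifeDistribution:
    """Leave-one-out estimates, one row per left-out case."""

    estimates: pd.DataFrame  # n x K

    @property
    def means(self) -> pd.Series:
        return self.estimates.mean(axis=0)


@dataclass
class ConfidenceInterval:
    parameter: str
    method: str  # 'percentile' | 'bca' | 'student_t'
    level: float  # confidence level 1 - alpha
    lower: float
    upper: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_indices(n: int, seed) -> np.ndarray:
    """Draw ``n`` row indices uniformly with replacement (deterministic per seed)."""
    if n < 2:
        raise ValueError("need at least 2 observations to resample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.integers(0, n, size=n)


def bootstrap_statistic(data, stat, B: int, seed, max_redraws: float = 0.1):
    """Generic bootstrap: ``B`` evaluations of ``stat`` on row-resampled data.

    ``stat`` maps an (m x J) array to a labeled :class:`pandas.Series` (or a
    1-D array).  Resamples on which ``stat`` raises
    :class:`~gscaboot.gsca.InadmissibleSampleError` are redrawn (not dropped),
    so exactly ``B`` replicates are returned; more than ``max_redraws * B``
    failures aborts.  Returns ``(replicates DataFrame, n_failed)``.
    """
    arr, _ = _as_matrix(data)
    n = arr.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    index = None
    n_failed = 0
    max_failed = int(np.ceil(max_redraws * B))
    while len(rows) < B:
        idx = resample_indices(n, rng)
        try:
            rep = stat(arr[idx])
        except InadmissibleSampleError:
            n_failed += 1
            if n_failed > max_failed:
                raise InadmissibleSampleError(
                    f"more than {max_failed} inadmissible resamples; data too degenerate"
                )
            continue
        if isinstance(rep, pd.Series):
            index = rep.index
            rep = rep.to_numpy()
        rows.append(np.asarray(rep, dtype=float))
    reps = pd.DataFrame(np.vstack(rows), columns=index)
    return reps, n_failed


def jackknife_statistic(data, stat) -> pd.DataFrame:
    """Leave-one-out evaluations of ``stat``; row ``i`` omits case ``i``."""
    arr, _ = _as_matrix(data)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("jackknife needs at least 3 observations")
    rows = []
    index = None
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        rep = stat(arr[mask])
        mask[i] = True
        if isinstance(rep, pd.Series):
            index = rep.index
            rep = rep.to_numpy()
        rows.append(np.asarray(rep, dtype=float))
    return pd.DataFrame(np.vstack(rows), columns=index)


def _indicator_matrix(data, spec: ModelSpec) -> np.ndarray:
    """Rows as ndarray in the spec's indicator order."""
    if isinstance(data, pd.DataFrame):
        missing = set(spec.indicators) - set(map(str, data.columns))
        if missing:
            raise ValueError(f"missing indicator columns: {sorted(missing)}")
        return data.loc[:, list(spec.indicators)].to_numpy(dtype=float)
    arr, _ = _as_matrix(data)
    if arr.shape[1] != spec.n_indicators:
        raise ValueError(
            f"data has {arr.shape[1]} columns, model expects {spec.n_indicators}"
        )
    return arr


def _gsca_stat(spec: ModelSpec, original: GSCAResult, tol: float, max_iter: int):
    comp = _compiled(spec)

    def stat(rows: np.ndarray) -> pd.Series:
        try:
            sd = standardize(rows, columns=spec.indicators)
        except ValueError as exc:  # constant column after resampling
            raise InadmissibleSampleError(str(exc)) from exc
        res = _fit_from_standardized(sd.values, comp, tol, max_iter)
        if not res.converged:
            raise InadmissibleSampleError("non-convergent refit")
        return sign_align(res, original).theta

    return stat


def bootstrap_distribution(
    data,
    spec: ModelSpec,
    original: GSCAResult,
    B: int,
    seed,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> BootstrapDistribution:
    """Bootstrap the full GSCA pipeline: resample rows, re-standardize, refit, align."""
    if not original.converged:
        raise ValueError("original solution did not converge; bootstrap undefined")
    arr = _indicator_matrix(data, spec)
    reps, n_failed = bootstrap_statistic(
        arr, _gsca_stat(spec, original, tol, max_iter), B, seed
    )
    return BootstrapDistribution(
        estimates=reps, original=original.theta.copy(), n=arr.shape[0], n_failed=n_failed
    )


def jackknife_distribution(
    data,
    spec: ModelSpec,
    original: GSCAResult,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> JackknifeDistribution:
    """Leave-one-out GSCA refits (for the BCa acceleration factor)."""
    if not original.converged:
        raise ValueError("original solution did not converge; jackknife undefined")
    arr = _indicator_matrix(data, spec)
    reps = jackknife_statistic(arr, _gsca_stat(spec, original, tol, max_iter))
    return JackknifeDistribution(estimates=reps)


# ---------------------------------------------------------------------------
# interval ingredients
# ---------------------------------------------------------------------------


def bootstrap_se(dist: BootstrapDistribution, parameter: str) -> float:
    """Standard deviation of the replicates (divisor B - 1)."""
    return float(dist.estimates[parameter].std(ddof=1))


def critical_ratio(estimate: float, se: float) -> float:
    """Bootstrap t statistic: estimate divided by its bootstrap standard error."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return estimate / se


def _round_half_up(x: float) -> int:
    # the 1e-9 guard keeps levels that are analytically exact (e.g. alpha/2
    # after a null BCa adjustment) from falling off a .5 boundary through
    # floating-point round-trip error
    return int(np.floor(x + 0.5 + 1e-9))


def _order_stat_index(level: float, B: int) -> int:
    """1-based order-statistic index: round(level * B) clamped to [1, B]."""
    return min(max(_round_half_up(level * B), 1), B)


def percentile_ci(
    dist: BootstrapDistribution, parameter: str, alpha: float = 0.05
) -> ConfidenceInterval:
    """Percentile interval between the alpha/2 and 1-alpha/2 order statistics."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    B = dist.B
    if B * alpha / 2.0 < 1.0:
        raise ValueError(f"too few resamples (B={B}) for alpha={alpha}")
    values = np.sort(dist.estimates[parameter].to_numpy())
    j = _order_stat_index(alpha / 2.0, B)
    k = _order_stat_index(1.0 - alpha / 2.0, B)
    return ConfidenceInterval(
        parameter=parameter,
        method="percentile",
        level=1.0 - alpha,
        lower=float(values[j - 1]),
        upper=float(values[k - 1]),
        diagnostics={"j": j, "k": k},
    )


def bias_correction(dist: BootstrapDistribution, parameter: str) -> float:
    """Bias-correction factor z0 = Phi^-1(#{theta* < theta_hat} / B).

    Ties between a replicate and the original estimate are not counted; the
    count is clamped to [0.5, B - 0.5] so z0 stays finite (the standard
    continuity correction for degenerate counts).
    """
    theta = dist.original[parameter]
    count = float(np.sum(dist.estimates[parameter].to_numpy() < theta))
    count = min(max(count, 0.5), dist.B - 0.5)
    return float(stats.norm.ppf(count / dist.B))


def acceleration(jack: JackknifeDistribution, parameter: str) -> float:
    """Jackknife acceleration a = sum(d^3) / (6 [sum(d^2)]^{3/2}), d = mean - leave-one-out."""
    vals = jack.estimates[parameter].to_numpy()
    d = vals.mean() - vals
    denom = 6.0 * np.sum(d**2) ** 1.5
    if denom == 0.0:
        return 0.0
    return float(np.sum(d**3) / denom)


def bca_ci(
    dist: BootstrapDistribution,
    jack: JackknifeDistribution,
    parameter: str,
    alpha: float = 0.05,
) -> ConfidenceInterval:
    """Bias-corrected and accelerated interval.

    Adjusted quantile levels::

        alpha_1 = Phi{ z0 + (z0 + z_(alpha/2)) / (1 - a (z0 + z_(alpha/2))) }
        alpha_2 = Phi{ z0 + (z0 + z_(1-alpha/2)) / (1 - a (z0 + z_(1-alpha/2))) }

    and the endpoints are the order statistics at those levels times B (same
    rounding rule as the percentile method).  Reduces exactly to the
    percentile interval when z0 = a = 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    B = dist.B
    if B * alpha / 2.0 < 1.0:
        raise ValueError(f"too few resamples (B={B}) for alpha={alpha}")
    z0 = bias_correction(dist, parameter)
    a = acceleration(jack, parameter)
    out = {}
    for tag, z in (("alpha1", stats.norm.ppf(alpha / 2.0)),
                   ("alpha2", stats.norm.ppf(1.0 - alpha / 2.0))):
        denom = 1.0 - a * (z0 + z)
        if denom == 0.0:
            raise ZeroDivisionError(
                f"BCa adjustment undefined for {parameter}: 1 - a(z0+z) = 0"
            )
        out[tag] = float(stats.norm.cdf(z0 + (z0 + z) / denom))
    values = np.sort(dist.estimates[parameter].to_numpy())
    j = _order_stat_index(out["alpha1"], B)
    k = _order_stat_index(out["alpha2"], B)
    return ConfidenceInterval(
        parameter=parameter,
        method="bca",
        level=1.0 - alpha,
        lower=float(values[j - 1]),
        upper=float(values[k - 1]),
        diagnostics={"z0": z0, "a": a, "alpha1": out["alpha1"], "alpha2": out["alpha2"],
                     "j": j, "k": k},
    )


def student_t_ci(
    estimate: float, se: float, n: int, alpha: float = 0.05, parameter: str = ""
) -> ConfidenceInterval:
    """Symmetric interval estimate +/- t_{n-1}(1-alpha/2) * bootstrap SE."""
    if n < 2:
        raise ValueError("need n >= 2 for the t interval")
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    return ConfidenceInterval(
        parameter=parameter,
        method="student_t",
        level=1.0 - alpha,
        lower=estimate - tq * se,
        upper=estimate + tq * se,
        diagnostics={"se": se, "t": tq, "df": n - 1},
    )


def confidence_intervals(
    dist: BootstrapDistribution,
    jack: JackknifeDistribution | None = None,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("percentile", "bca", "student_t"),
) -> pd.DataFrame:
    """All requested intervals for every parameter, as a tidy DataFrame."""
    if "bca" in methods and jack is None:
        raise ValueError("BCa intervals require a jackknife distribution")
    rows = []
    for parameter in dist.original.index:
        est = float(dist.original[parameter])
        se = bootstrap_se(dist, parameter)
        for method in methods:
            if method == "percentile":
                ci = percentile_ci(dist, parameter, alpha)
            elif method == "bca":
                ci = bca_ci(dist, jack, parameter, alpha)
            elif method == "student_t":
                ci = student_t_ci(est, se, dist.n, alpha, parameter=parameter)
            else:
                raise ValueError(f"unknown method {method!r}")
            d = ci.diagnostics
            rows.append(
                {
                    "parameter": parameter,
                    "method": method,
                    "level": ci.level,
                    "estimate": est,
                    "se": se,
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "z0": d.get("z0", np.nan),
                    "a": d.get("a", np.nan),
                    "alpha1": d.get("alpha1", np.nan),
                    "alpha2": d.get("alpha2", np.nan),
                }
            )
    return pd.DataFrame(rows)
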