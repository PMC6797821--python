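"""Coverage and balance scoring of simulated confidence intervals.

A replication's interval *covers* when ``lower <= theta <= upper``
(inclusive endpoints).  Non-coverage is split into ``miss_below`` (the
population value falls below the lower limit) and ``miss_above`` (above the
upper limit); the three proportions partition 1 exactly.  Aggregation
follows the reporting conventions of the study: loading results are
averaged (unweighted) over the six latent variables sharing a population
loading value, path results over the loading conditions sharing a
population path value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["coverage_balance", "aggregate_loadings", "aggregate_paths"]


def _require_columns(df: pd.DataFrame, cols: set[str]) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")


def coverage_balance(
    results: pd.DataFrame,
    theta_pop,
    by: tuple[str, ...] = ("condition", "parameter", "method"),
) -> pd.DataFrame:
    """Score coverage/miss_below/miss_above per key.

    Parameters
    ----------
    results : long-format table with columns condition, replication,
        parameter, method, lower, upper (as written by the harness).
    theta_pop : mapping parameter label -> population value.
    by : grouping key.

    Returns a table with columns ``coverage``, ``miss_below``, ``miss_above``
    (an exact ternary partition of 1) and ``n_effective``.
    """
    _require_columns(results, set(by) | {"parameter", "lower", "upper"})
    theta_pop = pd.Series(dict(theta_pop))
    unknown = set(results["parameter"]) - set(theta_pop.index)
    if unknown:
        raise ValueError(f"no population value for parameter(s): {sorted(unknown)}")
    df = results.copy()
    theta = theta_pop.loc[df["parameter"]].to_numpy()
    below = theta < df["lower"].to_numpy()
    above = theta > df["upper"].to_numpy()
    df["miss_below"] = below.astype(float)
    df["miss_above"] = above.astype(float)
    df["coverage"] = 1.0 - df["miss_below"] - df["miss_above"]
    grouped = df.groupby(list(by), sort=False).agg(
        coverage=("coverage", "mean"),
        miss_below=("miss_below", "mean"),
        miss_above=("miss_above", "mean"),
        n_effective=("coverage", "size"),
    )
    return grouped.reset_index()


def _attach_population_value(summary: pd.DataFrame, theta_pop) -> pd.DataFrame:
    theta_pop = pd.Series(dict(theta_pop))
    out = summary.copy()
    out["population_value"] = theta_pop.loc[out["parameter"]].to_numpy()
    return out


def _aggregate(summary: pd.DataFrame, theta_pop, prefix: str) -> pd.DataFrame:
    sub = _attach_population_value(summary, theta_pop)
    sub = sub[sub["parameter"].str.startswith(prefix)]
    if sub.empty:
        raise ValueError(f"no '{prefix}' rows to aggregate")
    keys = [c for c in ("condition", "method") if c in sub.columns] + ["population_value"]
    agg = sub.groupby(keys, sort=False).agg(
        coverage=("coverage", "mean"),
        miss_below=("miss_below", "mean"),
        miss_above=("miss_above", "mean"),
        n_parameters=("parameter", "nunique"),
        n_effective=("n_effective", "sum"),
    )
    return agg.reset_index()


def aggregate_loadings(summary: pd.DataFrame, theta_pop) -> pd.DataFrame:
    """Unweighted mean of per-latent summaries sharing a population loading value.

    In the default model each loading value (0.7, 0.8, 0.9) appears once per
    latent, so each aggregated row averages six per-parameter summaries.
    """
    return _aggregate(summary, theta_pop, "loading:")


def aggregate_paths(summary: pd.DataFrame, theta_pop) -> pd.DataFrame:
    """Per path-coefficient value, averaged over whatever conditions share it."""
    return _aggregate(summary, theta_pop, "path:")
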