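"""Monte Carlo harness: conditions x replications x bootstrap intervals.

Each replication generates one sample from the population model, fits the
GSCA model, draws ``B`` bootstrap refits plus one leave-one-out jackknife
pass, and records percentile, BCa and Student's t intervals for all free
parameters (18 loadings + 6 paths in the default model).  Results are
persisted as one long-format row per (condition, replication, parameter,
method), so scoring can be repeated without re-simulation.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .bootstrap import (
    bootstrap_distribution,
    confidence_intervals,
    jackknife_distribution,
)
from .gsca import GSCA
from .population import PopulationModel, build_population, generate

__all__ = ["SimulationDesign", "ReplicationRecord", "run_replication", "run_condition", "run_study"]

log = logging.getLogger(__name__)

METHODS = ("percentile", "bca", "student_t")


@dataclass
class SimulationDesign:
    """Factors of the Monte Carlo study (defaults reproduce the full design)."""

    distributions: tuple[str, ...] = ("normal", "lognormal")
    sample_sizes: tuple[int, ...] = (50, 100, 200, 500)
    n_replications: int = 500
    B: int = 1000
    alpha: float = 0.05
    methods: tuple[str, ...] = METHODS
    master_seed: int = 0
    tol: float = 1e-5
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.B * self.alpha / 2.0 < 1.0:
            raise ValueError("B * alpha / 2 must be at least 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def conditions(self) -> list[tuple[str, int]]:
        return [(d, n) for d in self.distributions for n in self.sample_sizes]


@dataclass
class ReplicationRecord:
    condition: str  # e.g. 'normal/n=100'
    replication: int
    converged: bool
    estimates: pd.Series | None
    intervals: pd.DataFrame | None  # one row per (parameter, method)
    n_failed_resamples: int = 0


def run_replication(
    model: PopulationModel,
    dist: str,
    n: int,
    B: int,
    alpha: float,
    methods: tuple[str, ...],
    seed: int,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> ReplicationRecord:
    """One full replication: sample, fit, bootstrap + jackknife, intervals."""
    condition = f"{dist}/n={n}"
    sample = generate(model, dist, n, seed)
    est = GSCA(spec=model.spec, tol=tol, max_iter=max_iter).fit(sample)
    if not est.converged_:
        return ReplicationRecord(condition, seed, False, None, None)
    original = est.result_
    dist_boot = bootstrap_distribution(
        sample, model.spec, original, B=B, seed=seed, tol=tol, max_iter=max_iter
    )
    jack = None
    if "bca" in methods:
        jack = jackknife_distribution(
            sample, model.spec, original, tol=tol, max_iter=max_iter
        )
    cis = confidence_intervals(dist_boot, jack, alpha=alpha, methods=tuple(methods))
    return ReplicationRecord(
        condition=condition,
        replication=seed,
        converged=True,
        estimates=original.theta,
        intervals=cis,
        n_failed_resamples=dist_boot.n_failed,
    )


def run_condition(
    model: PopulationModel,
    dist: str,
    n: int,
    design: SimulationDesign,
    condition_seed: int,
) -> list[ReplicationRecord]:
    """All replications of one design cell, with per-replication derived seeds."""
    records = []
    for r in range(design.n_replications):
        rec = run_replication(
            model,
            dist,
            n,
            B=design.B,
            alpha=design.alpha,
            methods=design.methods,
            seed=condition_seed + r,
            tol=design.tol,
            max_iter=design.max_iter,
        )
        rec.replication = r
        records.append(rec)
        if (r + 1) % 50 == 0:
            log.info("%s/n=%d: %d/%d replications", dist, n, r + 1, design.n_replications)
    return records


def records_to_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    """Long format: one row per (condition, replication, parameter, method)."""
    frames = []
    for rec in records:
        if not rec.converged:
            continue
        df = rec.intervals.copy()
        df.insert(0, "condition", rec.condition)
        df.insert(1, "replication", rec.replication)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["condition", "replication", "parameter", "method",
                     "level", "estimate", "se", "lower", "upper"]
        )
    return pd.concat(frames, ignore_index=True)


def run_study(
    design: SimulationDesign,
    model: PopulationModel | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run every design cell; return (long results table, manifest).

    If ``out_dir`` is given, writes ``results.csv`` and ``manifest.json``
    there (each cell is appended as it completes, so a partial run preserves
    the cells finished so far).
    """
    if model is None:
        model = build_population()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    all_frames: list[pd.DataFrame] = []
    counts: dict[str, dict[str, int]] = {}
    for c_index, (dist, n) in enumerate(design.conditions):
        cond_seed = design.master_seed + c_index * design.n_replications
        records = run_condition(model, dist, n, design, cond_seed)
        frame = records_to_frame(records)
        n_nonconv = sum(1 for r in records if not r.converged)
        counts[f"{dist}/n={n}"] = {
            "replications": len(records),
            "non_convergent": n_nonconv,
            "inadmissible_resamples_redrawn": int(
                sum(r.n_failed_resamples for r in records)
            ),
        }
        all_frames.append(frame)
        if out_path is not None:
            mode = "w" if c_index == 0 else "a"
            frame.to_csv(out_path / "results.csv", mode=mode, header=c_index == 0, index=False)
    results = pd.concat(all_frames, ignore_index=True)
    manifest = {
        "design": asdict(design),
        "theta_pop": model.theta_pop.to_dict(),
        "cells": counts,
        "package_version": _version,
        "python": sys.version.split()[0],
    }
    if out_path is not None:
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results, manifest
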