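"""Population model and synthetic data generation for the simulation study.

The data-generating model has six latent variables — four exogenous
(gamma1..gamma4) and two endogenous (gamma5, gamma6) — each measured by
three indicators with standardized loadings 0.7, 0.8 and 0.9.  Six
structural paths carry the coefficients {-0.75, -0.25, -0.2, -0.15, 0.35,
0.55}; with the default wiring and exogenous correlations below, the
explained variances of the endogenous latents are R^2 = 0.168 (gamma5)
and 0.383 (gamma6).

Two indicator distributions are supported:

* ``normal`` — i.i.d. multivariate normal rows with the model-implied
  indicator correlation matrix ``sigma`` (standard normals mixed with the
  lower Cholesky factor of ``sigma``);
* ``lognormal`` — independent standard normals are exponentiated, each
  column is standardized, and the matrix is post-multiplied by the
  transpose of the lower Cholesky factor of ``sigma``.  The marginals are
  strongly right-skewed and heavy-tailed while the correlation structure
  matches ``sigma`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec

__all__ = [
    "PopulationModel",
    "DEFAULT_PATHS",
    "DEFAULT_LOADINGS",
    "default_exo_corr",
    "build_population",
    "latent_covariance",
    "population_r2",
    "implied_sigma",
    "generate_normal",
    "generate_lognormal",
    "generate",
    "moments",
    "average_moments",
]

#: Structural paths (source, target, coefficient) of the default population model.
DEFAULT_PATHS: tuple[tuple[str, str, float], ...] = (
    ("gamma1", "gamma5", -0.25),
    ("gamma2", "gamma5", -0.20),
    ("gamma3", "gamma5", 0.55),
    ("gamma1", "gamma6", -0.75),
    ("gamma4", "gamma6", 0.35),
    ("gamma5", "gamma6", -0.15),
)

#: Standardized loadings of each latent's three indicators.
DEFAULT_LOADINGS: tuple[float, float, float] = (0.7, 0.8, 0.9)

_EXO = ("gamma1", "gamma2", "gamma3", "gamma4")


def default_exo_corr() -> np.ndarray:
    """Correlations among the four exogenous latents (0.6, except 0.5 for gamma3-gamma4)."""
    phi = np.full((4, 4), 0.6)
    np.fill_diagonal(phi, 1.0)
    phi[2, 3] = phi[3, 2] = 0.5
    return phi


@dataclass
class PopulationModel:
    """A fully specified population GSCA model with implied covariances."""

    spec: ModelSpec
    loadings: pd.Series  # per-indicator population loadings
    paths: tuple[tuple[str, str, float], ...]
    exo_corr: np.ndarray  # correlations among exogenous latents
    latent_cov: np.ndarray  # P x P implied latent correlation matrix
    sigma: np.ndarray  # J x J implied indicator correlation matrix
    theta_pop: pd.Series  # labeled true loadings and paths
    r2: dict[str, float]  # explained variance per endogenous latent
    structure: str = "component"


def _topological(spec: ModelSpec) -> list[str]:
    order: list[str] = []
    remaining = set(spec.components)
    while remaining:
        ready = [
            c for c in spec.components
            if c in remaining and all(p not in remaining for p in spec.predecessors(c))
        ]
        if not ready:
            raise ValueError("structural paths contain a cycle")
        order.extend(ready)
        remaining -= set(ready)
    return order


def latent_covariance(
    spec: ModelSpec,
    paths: tuple[tuple[str, str, float], ...],
    exo_corr: np.ndarray,
) -> tuple[np.ndarray, dict[str, float]]:
    """Implied latent correlation matrix under unit-variance residual scaling.

    Exogenous latents have the given correlations; each endogenous latent is a
    linear combination of its predictors plus an independent residual whose
    variance is chosen so the latent has variance exactly 1.  Returns the
    P x P matrix and the explained variance (R^2) of each endogenous latent.
    """
    comps = list(spec.components)
    P = len(comps)
    exo = [c for c in comps if not spec.predecessors(c)]
    if exo_corr.shape != (len(exo), len(exo)):
        raise ValueError("exo_corr dimension does not match the exogenous latents")
    coef = {(s, d): v for s, d, v in paths}
    phi = np.full((P, P), np.nan)
    for i, ci in enumerate(exo):
        for j, cj in enumerate(exo):
            phi[comps.index(ci), comps.index(cj)] = exo_corr[i, j]
    r2: dict[str, float] = {}
    for c in _topological(spec):
        q = comps.index(c)
        preds = spec.predecessors(c)
        if not preds:
            continue
        S = [comps.index(p) for p in preds]
        b = np.array([coef[(p, c)] for p in preds])
        explained = float(b @ phi[np.ix_(S, S)] @ b)
        if explained >= 1.0:
            raise ValueError(
                f"implied residual variance of {c} is non-positive "
                f"(explained variance {explained:.3f} >= 1)"
            )
        r2[c] = explained
        cov_row = phi[S, :] .T @ b  # cov with everything already known
        phi[q, :] = cov_row
        phi[:, q] = cov_row
        phi[q, q] = 1.0
    np.linalg.cholesky(phi)  # positive definiteness check
    return phi, r2


def _component_block(lam: np.ndarray) -> np.ndarray:
    """Unit-diagonal within-block correlation matrix with ``Sigma lam = (lam'lam) lam``.

    Making the loading vector the top eigenvector of its block is what renders
    the component (composite) model self-consistent: the unit-variance
    composite built from the block reproduces exactly the stated loadings as
    indicator-composite correlations, and GSCA's weight update is stationary
    at the population weights ``w = lam / (lam'lam)``.
    """
    k = lam.size
    if k == 1:
        return np.ones((1, 1))
    s = float(lam @ lam)
    rhs = (s - 1.0) * lam
    # unknowns: off-diagonal correlations rho_{jk}; row j gives
    # sum_{k != j} rho_{jk} lam_k = (s - 1) lam_j
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    A = np.zeros((k, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        A[i, col] = lam[j]
        A[j, col] = lam[i]
    sol, residual, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < min(A.shape) and not np.allclose(A @ sol, rhs):
        raise ValueError("no self-consistent within-block correlation structure")
    if not np.allclose(A @ sol, rhs):
        raise ValueError(
            f"loadings {lam.tolist()} admit no unit-diagonal block with the "
            "loading vector as eigenvector"
        )
    block = np.eye(k)
    for col, (i, j) in enumerate(pairs):
        block[i, j] = block[j, i] = sol[col]
    return block


def implied_sigma(
    spec: ModelSpec,
    loadings: pd.Series,
    latent_cov: np.ndarray,
    structure: str = "component",
) -> tuple[np.ndarray, pd.Series]:
    """Implied indicator correlation matrix and the population loading vector.

    ``structure='component'`` (default) builds the composite-model
    covariance: within each block, a unit-diagonal matrix whose top
    eigenvector is the block loading vector (eigenvalue ``lam'lam``);
    between blocks, ``Sigma_pq = phi_pq lam_p lam_q'``.  Under this
    construction the stated loadings and paths are exactly the population
    values of the GSCA estimator (the estimator is Fisher-consistent for
    them), which is what a coverage study of the estimator's confidence
    intervals requires.

    ``structure='factor'`` treats the stated loadings as common-factor
    loadings: within-block covariances ``lam_i lam_j`` with unique variances
    ``1 - lam^2`` on the diagonal.  Composite loadings on factor-generated
    data exceed the factor loadings, so GSCA is *not* consistent for the
    stated values under this mode; it is provided for studying that
    discrepancy, not for the coverage study.
    """
    comps = list(spec.components)
    J = spec.n_indicators
    lam = loadings.loc[list(spec.indicators)].to_numpy(dtype=float)
    if structure == "factor":
        L = np.zeros((J, len(comps)))
        for p, c in enumerate(comps):
            F = spec.block_indices(c)
            L[F, p] = lam[F]
        sigma = L @ latent_cov @ L.T
        sigma[np.diag_indices(J)] = 1.0
    elif structure == "component":
        sigma = np.zeros((J, J))
        for p, c in enumerate(comps):
            F = spec.block_indices(c)
            sigma[np.ix_(F, F)] = _component_block(lam[F])
        for p, cp in enumerate(comps):
            Fp = spec.block_indices(cp)
            for q in range(p + 1, len(comps)):
                Fq = spec.block_indices(comps[q])
                cross = latent_cov[p, q] * np.outer(lam[Fp], lam[Fq])
                sigma[np.ix_(Fp, Fq)] = cross
                sigma[np.ix_(Fq, Fp)] = cross.T
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.linalg.cholesky(sigma)  # positive definiteness check
    return sigma, pd.Series(lam.copy(), index=list(spec.indicators))


def build_population(
    paths: tuple[tuple[str, str, float], ...] = DEFAULT_PATHS,
    loadings=DEFAULT_LOADINGS,
    exo_corr: np.ndarray | None = None,
    n_blocks: int = 6,
    structure: str = "component",
) -> PopulationModel:
    """Construct the six-latent population model.

    ``loadings`` may be a per-block triple applied to every block (default
    ``(0.7, 0.8, 0.9)``) or a mapping component -> triple.
    """
    comps = [f"gamma{p + 1}" for p in range(n_blocks)]
    blocks = {}
    k = 0
    for c in comps:
        blocks[c] = [f"x{k + 1}", f"x{k + 2}", f"x{k + 3}"]
        k += 3
    spec = ModelSpec(blocks=blocks, paths=[(s, d) for s, d, _ in paths])
    if exo_corr is None:
        exo_corr = default_exo_corr()
    exo_corr = np.asarray(exo_corr, dtype=float)
    if not np.allclose(exo_corr, exo_corr.T) or not np.allclose(np.diag(exo_corr), 1.0):
        raise ValueError("exo_corr must be a correlation matrix")

    if isinstance(loadings, dict):
        lam_map = {c: tuple(loadings[c]) for c in comps}
    else:
        lam_map = {c: tuple(loadings) for c in comps}
    lam = pd.Series(
        {ind: lam_map[c][i] for c, members in blocks.items() for i, ind in enumerate(members)}
    ).loc[list(spec.indicators)]

    phi, r2 = latent_covariance(spec, paths, exo_corr)
    sigma, true_lam = implied_sigma(spec, lam, phi, structure=structure)

    theta = pd.Series(
        np.concatenate([true_lam.to_numpy(), [v for _, _, v in paths]]),
        index=list(spec.parameter_labels),
    )
    return PopulationModel(
        spec=spec,
        loadings=true_lam,
        paths=tuple(paths),
        exo_corr=exo_corr,
        latent_cov=phi,
        sigma=sigma,
        theta_pop=theta,
        r2=r2,
        structure=structure,
    )


def population_r2(model: PopulationModel, endogenous: str) -> float:
    """Explained variance of an endogenous latent (1 - residual variance)."""
    if endogenous not in model.r2:
        raise ValueError(f"{endogenous!r} has no predictors in the population model")
    return model.r2[endogenous]


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_normal(model: PopulationModel, n: int, seed) -> pd.DataFrame:
    """Multivariate normal rows with covariance ``model.sigma``."""
    if n < 20:
        raise ValueError("need n >= 20")
    L = np.linalg.cholesky(model.sigma)
    X = _rng(seed).standard_normal((n, model.spec.n_indicators)) @ L.T
    return pd.DataFrame(X, columns=list(model.spec.indicators))


def generate_lognormal(model: PopulationModel, n: int, seed) -> pd.DataFrame:
    """Lognormal-transformed rows with target covariance ``model.sigma``.

    Independent standard normals are exponentiated, each column standardized
    (divisor-n convention), and the matrix mixed with the transpose of the
    lower Cholesky factor of ``sigma``.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    J = model.spec.n_indicators
    U = _rng(seed).standard_normal((n, J))
    E = np.exp(U)
    E = E - E.mean(axis=0)
    E = E / np.sqrt(np.einsum("ij,ij->j", E, E) / n)
    L = np.linalg.cholesky(model.sigma)
    return pd.DataFrame(E @ L.T, columns=list(model.spec.indicators))


def generate(model: PopulationModel, dist: str, n: int, seed) -> pd.DataFrame:
    if dist == "normal":
        return generate_normal(model, n, seed)
    if dist == "lognormal":
        return generate_lognormal(model, n, seed)
    raise ValueError(f"unknown distribution {dist!r}")


# ---------------------------------------------------------------------------
# sample moments
# ---------------------------------------------------------------------------


def moments(data) -> pd.DataFrame:
    """Per-column skewness and kurtosis (fourth standardized moment; normal = 3).

    Uses divisor-n central moments with no bias adjustment and no excess
    correction — kurtosis of a normal sample is near 3, not 0.
    """
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
        cols = list(data.columns)
    else:
        arr = np.asarray(data, dtype=float)
        cols = [f"col{j}" for j in range(arr.shape[1])]
    c = arr - arr.mean(axis=0)
    m2 = np.mean(c**2, axis=0)
    if np.any(m2 <= 0):
        bad = [cols[j] for j in np.flatnonzero(m2 <= 0)]
        raise ValueError(f"zero-variance column(s): {bad}")
    skew = np.mean(c**3, axis=0) / m2**1.5
    kurt = np.mean(c**4, axis=0) / m2**2
    return pd.DataFrame({"skewness": skew, "kurtosis": kurt}, index=cols)


def average_moments(
    model: PopulationModel,
    dist: str,
    n: int,
    n_replications: int,
    seed: int,
) -> pd.DataFrame:
    """Per-indicator skewness/kurtosis averaged over seeded replications."""
    acc = None
    for r in range(n_replications):
        m = moments(generate(model, dist, n, seed + r))
        acc = m if acc is None else acc + m
    return acc / n_replications
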