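"""GSCA estimation by alternating least squares.

Generalized structured component analysis represents each construct as a
unit-variance weighted composite of its indicator block and minimizes one
least-squares criterion

    f = SS(Z - Gamma C) + sum_{q endogenous} SS(gamma_q - Gamma b_q),

where ``Z`` is the column-standardized data, ``Gamma = Z W`` the component
scores, ``C`` the loading matrix and ``b_q`` the path coefficients into an
endogenous component.  The alternating least squares (ALS) scheme iterates

1. given weights: free loadings and paths solve per-column ordinary least
   squares problems,
2. given loadings/paths: each component's weights solve the criterion's
   least-squares subproblem under the unit-variance constraint on the
   component score (solved exactly, so the fit never increases).

All standardization uses the divisor-``n`` convention, so component variances
are ``w' (Z'Z / n) w`` and the ALS can run entirely on the J x J sample
correlation matrix — an important economy for bootstrap refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import ModelSpec

__all__ = [
    "GSCA",
    "GSCAResult",
    "InadmissibleSampleError",
    "StandardizedData",
    "standardize",
    "fit_criterion",
    "fit_gsca",
    "sign_align",
]


class InadmissibleSampleError(ValueError):
    """A (re)sample on which the model cannot be estimated.

    Raised for constant indicator columns after resampling or singular
    within-block systems; bootstrap machinery treats these as inadmissible
    replications and redraws.
    """


@dataclass(frozen=True)
class StandardizedData:
    """Column-standardized data: each column has mean 0 and sum of squares n."""

    values: np.ndarray
    columns: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_matrix(raw) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(raw, StandardizedData):
        return raw.values, raw.columns
    if isinstance(raw, pd.DataFrame):
        return raw.to_numpy(dtype=float), tuple(map(str, raw.columns))
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    return arr, tuple(f"col{j}" for j in range(arr.shape[1]))


def standardize(raw, columns: tuple[str, ...] | None = None) -> StandardizedData:
    """Center and scale each column to mean 0 and sum of squares ``n``.

    Uses the divisor-``n`` convention (population variance 1), which makes
    the GSCA unit-variance normalization ``diag(W'Z'ZW) = n I`` exact.
    Idempotent on already-standardized input.
    """
    arr, cols = _as_matrix(raw)
    if columns is not None:
        cols = tuple(columns)
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("data contain non-finite values")
    centered = arr - arr.mean(axis=0)
    ss = np.einsum("ij,ij->j", centered, centered)
    bad = np.flatnonzero(ss <= 0)
    if bad.size:
        raise ValueError(f"constant column(s): {[cols[j] for j in bad]}")
    z = centered / np.sqrt(ss / n)
    return StandardizedData(values=z, columns=cols)


# ---------------------------------------------------------------------------
# compiled structural layout (index arrays shared by the hot loops)
# ---------------------------------------------------------------------------


class _Compiled:
    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.J = spec.n_indicators
        self.P = spec.n_components
        self.blocks = [spec.block_indices(c) for c in spec.components]
        self.block_of = np.array(
            [spec.component_index(spec.block_of[ind]) for ind in spec.indicators]
        )
        mask = spec.path_pattern
        self.preds = [np.flatnonzero(mask[:, q]) for q in range(self.P)]
        self.endo = [q for q in range(self.P) if self.preds[q].size]
        self.succ = [
            [q for q in self.endo if p in self.preds[q]] for p in range(self.P)
        ]
        self.path_idx = [
            (spec.component_index(s), spec.component_index(d)) for s, d in spec.paths
        ]
        self.labels = spec.parameter_labels


def _solve_ls(G: np.ndarray, v: np.ndarray, what: str) -> np.ndarray:
    """Solve G x = v; on a singular system fall back to the minimum-norm
    least-squares solution, accepted only if it is consistent (so perfectly
    redundant indicators remain estimable while contradictory systems are
    flagged inadmissible)."""
    try:
        x = np.linalg.solve(G, v)
        if np.all(np.isfinite(x)):
            return x
    except np.linalg.LinAlgError:
        pass
    x, *_ = np.linalg.lstsq(G, v, rcond=None)
    if not np.all(np.isfinite(x)) or not np.allclose(G @ x, v, atol=1e-8):
        raise InadmissibleSampleError(f"singular {what}")
    return x


_COMPILED_CACHE: dict[int, _Compiled] = {}


def _compiled(spec: ModelSpec) -> _Compiled:
    key = id(spec)
    hit = _COMPILED_CACHE.get(key)
    if hit is None or hit.spec is not spec:
        hit = _Compiled(spec)
        _COMPILED_CACHE[key] = hit
        if len(_COMPILED_CACHE) > 64:  # keep the cache bounded
            _COMPILED_CACHE.pop(next(iter(_COMPILED_CACHE)))
    return hit


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class GSCAResult:
    """Estimated GSCA parameters at (or at termination of) the ALS.

    ``theta`` is the flat labeled vector of free loadings followed by free
    paths — the parameter vector consumed by the bootstrap machinery.
    """

    weights: np.ndarray  # J x P, zero off-block
    loadings: np.ndarray  # P x J, zero off-block
    paths: np.ndarray  # P x P, zero where no path
    fit: float
    n_iterations: int
    converged: bool
    theta: pd.Series
    fit_history: tuple[float, ...] = ()
    path_idx: tuple[tuple[int, int], ...] = ()  # (src, dst) per theta path entry


def _theta(comp: _Compiled, lam: np.ndarray, B: np.ndarray) -> pd.Series:
    vals = np.concatenate([lam, [B[i, j] for i, j in comp.path_idx]])
    return pd.Series(vals, index=list(comp.labels))


def _expand(comp: _Compiled, W: np.ndarray, lam: np.ndarray, B: np.ndarray):
    C = np.zeros((comp.P, comp.J))
    C[comp.block_of, np.arange(comp.J)] = lam
    return W, C, B


# ---------------------------------------------------------------------------
# core ALS on the correlation matrix
# ---------------------------------------------------------------------------


def _criterion_from_corr(comp, R, W, lam, B, n):
    M = R @ W
    K = W.T @ M
    meas = np.sum(1.0 + lam**2 - 2.0 * lam * M[np.arange(comp.J), comp.block_of])
    struct = 0.0
    for q in comp.endo:
        b = B[:, q]
        struct += 1.0 + b @ K @ b - 2.0 * b @ K[:, q]
    return n * (meas + struct)


def _als_from_corr(
    R: np.ndarray,
    n: int,
    comp: _Compiled,
    tol: float,
    max_iter: int,
    init_weights: np.ndarray | None = None,
):
    J, P = comp.J, comp.P
    W = np.zeros((J, P))
    for p, F in enumerate(comp.blocks):
        w0 = np.ones(F.size) if init_weights is None else init_weights[F, p].copy()
        var = w0 @ R[np.ix_(F, F)] @ w0
        if not np.isfinite(var) or var <= 1e-12:
            raise InadmissibleSampleError(f"degenerate block {comp.spec.components[p]}")
        W[F, p] = w0 / np.sqrt(var)

    lam = np.zeros(J)
    B = np.zeros((P, P))
    history: list[float] = []
    f_prev = np.inf
    converged = False
    it = 0
    cols = np.arange(J)
    for it in range(1, max_iter + 1):
        M = R @ W  # J x P
        # -- loadings: one regressor each, component variance is 1
        lam = M[cols, comp.block_of]
        # -- paths: per endogenous component OLS on its predictors
        K = W.T @ M
        for q in comp.endo:
            S = comp.preds[q]
            B[S, q] = _solve_ls(K[np.ix_(S, S)], K[S, q], "structural system")
        # -- weights: exact constrained minimizer, coordinate sweep over components
        for p in range(P):
            F = comp.blocks[p]
            v = R[np.ix_(F, F)] @ lam[F]
            if comp.preds[p].size:
                v = v + R[F, :] @ (W @ B[:, p])
            for q in comp.succ[p]:
                u = W[:, q] - W @ B[:, q] + B[p, q] * W[:, p]
                v = v + B[p, q] * (R[F, :] @ u)
            G = R[np.ix_(F, F)]
            x = _solve_ls(G, v, f"indicator block {comp.spec.components[p]}")
            denom = v @ x
            if not np.isfinite(denom) or denom <= 1e-14:
                raise InadmissibleSampleError(
                    f"degenerate weight update for {comp.spec.components[p]}"
                )
            W[:, p] = 0.0
            W[F, p] = x / np.sqrt(denom)
        f = _criterion_from_corr(comp, R, W, lam, B, n)
        history.append(f)
        if f_prev - f < tol:
            converged = f_prev - f > -1e-8  # guard: an increase is non-convergence
            break
        f_prev = f
    return W, lam, B, history[-1], it, converged, tuple(history)


def _fit_from_standardized(
    z: np.ndarray, comp: _Compiled, tol: float, max_iter: int, init_weights=None
) -> GSCAResult:
    n = z.shape[0]
    R = (z.T @ z) / n
    W, lam, B, f, it, conv, hist = _als_from_corr(
        R, n, comp, tol, max_iter, init_weights
    )
    W, lam, B = _apply_sign_convention(comp, W, lam, B)
    _, C, _ = _expand(comp, W, lam, B)
    return GSCAResult(
        weights=W,
        loadings=C,
        paths=B,
        fit=f,
        n_iterations=it,
        converged=conv,
        theta=_theta(comp, lam, B),
        fit_history=hist,
        path_idx=tuple(comp.path_idx),
    )


def _apply_sign_convention(comp, W, lam, B):
    """Flip each component so the sum of its loadings is >= 0 (ties keep)."""
    for p in range(comp.P):
        F = comp.blocks[p]
        if lam[F].sum() < 0:
            W[:, p] = -W[:, p]
            lam[F] = -lam[F]
            B[p, :] = -B[p, :]
            B[:, p] = -B[:, p]
    return W, lam, B


# ---------------------------------------------------------------------------
# public functional surface
# ---------------------------------------------------------------------------


def fit_criterion(data, spec: ModelSpec, weights, loadings, paths) -> float:
    """Evaluate the GSCA least-squares criterion at the given parameters.

    The measurement part regresses every indicator on its component; the
    structural part regresses every endogenous component on its predictors.
    Computed directly from the standardized data matrix (this is the slow,
    obviously-correct form; the ALS uses an algebraically equal correlation-
    space form).
    """
    sd = data if isinstance(data, StandardizedData) else standardize(data)
    z = sd.values
    W = np.asarray(weights, dtype=float)
    C = np.asarray(loadings, dtype=float)
    B = np.asarray(paths, dtype=float)
    J, P = spec.n_indicators, spec.n_components
    if W.shape != (J, P) or C.shape != (P, J) or B.shape != (P, P):
        raise ValueError("parameter dimensions do not match the model spec")
    gamma = z @ W
    f = float(np.sum((z - gamma @ C) ** 2))
    comp = _compiled(spec)
    for q in comp.endo:
        f += float(np.sum((gamma[:, q] - gamma @ B[:, q]) ** 2))
    return f


def fit_gsca(
    data,
    spec: ModelSpec,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> GSCAResult:
    """Standardize ``data`` and estimate the GSCA model (thin wrapper over :class:`GSCA`)."""
    sd = data if isinstance(data, StandardizedData) else standardize(data)
    return _fit_from_standardized(sd.values, _compiled(spec), tol, max_iter)


def sign_align(candidate: GSCAResult, reference: GSCAResult) -> GSCAResult:
    """Resolve component sign indeterminacy against a reference solution.

    For each component, flips its weights column, loadings row and incident
    path coefficients if the inner product of candidate and reference weight
    vectors is negative (exact zero keeps the candidate).  The fit value is
    invariant under these flips.
    """
    W = candidate.weights.copy()
    C = candidate.loadings.copy()
    B = candidate.paths.copy()
    theta = candidate.theta.copy()
    J, P = W.shape
    flipped = np.zeros(P, dtype=bool)
    for p in range(P):
        if W[:, p] @ reference.weights[:, p] < 0:
            flipped[p] = True
            W[:, p] = -W[:, p]
            C[p, :] = -C[p, :]
            B[p, :] = -B[p, :]
            B[:, p] = -B[:, p]
    if flipped.any():
        theta.iloc[:J] = C.sum(axis=0)  # one nonzero loading per indicator
        for k, (src, dst) in enumerate(candidate.path_idx):
            theta.iloc[J + k] = B[src, dst]
    return GSCAResult(
        weights=W,
        loadings=C,
        paths=B,
        fit=candidate.fit,
        n_iterations=candidate.n_iterations,
        converged=candidate.converged,
        theta=theta,
        fit_history=candidate.fit_history,
        path_idx=candidate.path_idx,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------


class GSCA(BaseEstimator, TransformerMixin):
    """Generalized structured component analysis estimator.

    Parameters
    ----------
    spec : ModelSpec
        Block membership of indicators and the structural path pattern.
    tol : float, default 1e-5
        Convergence threshold on the absolute decrease of the least-squares
        criterion between ALS iterations.
    max_iter : int, default 300
        Maximum number of ALS iterations.
    random_restarts : int, default 0
        Additional ALS runs from seeded random weight initializations; the
        solution with the lowest criterion is kept.  The default deterministic
        initialization (all free weights equal) is adequate for well-behaved
        blocks.
    random_state : int or None
        Seed for the random restarts.

    Attributes
    ----------
    weights_ : ndarray of shape (J, P)
        Component weights (zero outside each component's block).
    loadings_ : ndarray of shape (P, J)
        Loadings (zero outside each block); with standardized data these are
        the correlations between indicators and their component.
    paths_ : ndarray of shape (P, P)
        Path coefficients, entry (i, j) for the path component_i -> component_j.
    fit_ : float
        Least-squares criterion at termination.
    converged_ : bool
    n_iter_ : int
    theta_ : pandas.Series
        Labeled free loadings and paths.
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        tol: float = 1e-5,
        max_iter: int = 300,
        random_restarts: int = 0,
        random_state: int | None = None,
    ):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter
        self.random_restarts = random_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.spec is None:
            raise ValueError("GSCA requires a model spec")
        spec = self.spec
        if isinstance(X, pd.DataFrame):
            missing = set(spec.indicators) - set(map(str, X.columns))
            if missing:
                raise ValueError(f"missing indicator columns: {sorted(missing)}")
            arr = X.loc[:, list(spec.indicators)].to_numpy(dtype=float)
        else:
            arr, _ = _as_matrix(X)
            if arr.shape[1] != spec.n_indicators:
                raise ValueError(
                    f"X has {arr.shape[1]} columns, model expects {spec.n_indicators}"
                )
        comp = _compiled(spec)
        self._means = arr.mean(axis=0)
        centered = arr - self._means
        ss = np.einsum("ij,ij->j", centered, centered)
        bad = np.flatnonzero(ss <= 0)
        if bad.size:
            raise ValueError(
                f"constant column(s): {[spec.indicators[j] for j in bad]}"
            )
        if arr.shape[0] < 3:
            raise ValueError("need at least 3 observations")
        self._scales = np.sqrt(ss / arr.shape[0])
        z = centered / self._scales
        best = _fit_from_standardized(z, comp, self.tol, self.max_iter)
        if self.random_restarts:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.random_restarts):
                init = np.zeros_like(best.weights)
                for p, F in enumerate(comp.blocks):
                    init[F, p] = rng.normal(size=F.size)
                try:
                    cand = _fit_from_standardized(
                        z, comp, self.tol, self.max_iter, init_weights=init
                    )
                except InadmissibleSampleError:
                    continue
                if cand.fit < best.fit:
                    best = cand
        self.result_ = best
        self.weights_ = best.weights
        self.loadings_ = best.loadings
        self.paths_ = best.paths
        self.fit_ = best.fit
        self.n_iter_ = best.n_iterations
        self.converged_ = best.converged
        self.fit_history_ = best.fit_history
        self.theta_ = best.theta
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        """Component scores of ``X`` under the fitted weights (training scale)."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("GSCA instance is not fitted")
        arr, _ = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            arr = X.loc[:, list(self.spec.indicators)].to_numpy(dtype=float)
        z = (arr - self._means) / self._scales
        return z @ self.weights_
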