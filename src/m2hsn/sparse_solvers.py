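"""Sparse-recovery engines: OMP and Smoothed-ℓ0 (SL0).

OMP is the greedy solver used inside dictionary training; SL0 is the solver
used for reconstruction.  SL0 approximates the ℓ0 "norm" by a sum of Gaussian
bumps Σ exp(−x_i²/2σ²) and maximises it over the affine solution set
{x : Ax = y}: starting from the minimum-ℓ2-norm solution, it alternates small
gradient steps with projection back onto the constraint, while σ is annealed
downward.  The noiseless, equality-constrained variant is used because
measurements here are exact band selections.

A practical consequence worth knowing: when A is square and invertible the
solution set is a single point, so SL0 degenerates to the ℓ2 solution — this
is why dictionary-based reconstruction misbehaves when the dictionary size
equals the number of measured bands.

``sl0`` accepts a batch of right-hand sides (columns of a 2-D ``y``); all
per-pixel reconstructions in the toolkit share one system matrix, so batching
does the heavy lifting in a handful of BLAS calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import BudgetError, DimensionError, InputError

#: Relative magnitude below which a coefficient is reported as zero.
SUPPORT_THRESHOLD = 1e-6


@dataclass(frozen=True)
class SparseCode:
    """Result of a sparse solve: dense coefficients plus their support."""

    coefficients: np.ndarray
    support: np.ndarray

    @property
    def n_nonzero(self) -> int:
        return int(self.support.size)


@dataclass(frozen=True)
class SL0Params:
    """SL0 annealing schedule (defaults follow the original SL0 recipe)."""

    sigma_min: float = 1e-4
    sigma_decrease: float = 0.5
    mu: float = 2.0
    inner_iterations: int = 3

    def __post_init__(self) -> None:
        if self.sigma_min <= 0 or not 0 < self.sigma_decrease < 1:
            raise InputError("need sigma_min > 0 and sigma_decrease in (0, 1)")
        if self.mu <= 0 or self.inner_iterations < 1:
            raise InputError("need mu > 0 and inner_iterations >= 1")


def support_of(x: np.ndarray, threshold: float = SUPPORT_THRESHOLD) -> np.ndarray:
    """Indices with magnitude above ``threshold`` times the largest magnitude."""
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0.0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(x) > threshold * peak)


# ---------------------------------------------------------------------------
# OMP
# ---------------------------------------------------------------------------

def omp(A: np.ndarray, y: np.ndarray, T: int, residual_tol: float = 1e-12) -> SparseCode:
    """Orthogonal Matching Pursuit with at most ``T`` atoms.

    Greedily picks the column most correlated with the residual, refits by
    least squares on the selected support, and stops after ``T`` atoms or
    when the residual norm drops below ``residual_tol``.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, k = A.shape
    if y.shape != (m,):
        raise DimensionError(f"y has length {y.size}, A has {m} rows")
    if not 1 <= T <= min(m, k):
        raise InputError(f"need 1 <= T <= min(M, K) = {min(m, k)}, got T={T}")
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise InputError("A contains an all-zero column")

    residual = y.copy()
    support: list[int] = []
    coef = np.zeros(k)
    prev_norm = np.linalg.norm(residual)
    for _ in range(T):
        if prev_norm < residual_tol:
            break
        corr = np.abs(A.T @ residual) / norms
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        support.append(j)
        As = A[:, support]
        sol, _, rank, _ = scipy.linalg.lstsq(As, y, lapack_driver="gelsd")
        if rank < len(support):
            warnings.warn("singular support system in OMP; ridge fallback", stacklevel=2)
            gram = As.T @ As + 1e-10 * np.eye(len(support))
            sol = np.linalg.solve(gram, As.T @ y)
        residual = y - As @ sol
        new_norm = np.linalg.norm(residual)
        # greedy LS refits can never increase the residual
        assert new_norm <= prev_norm + 1e-10
        prev_norm = new_norm
        coef = np.zeros(k)
        coef[support] = sol
    return SparseCode(coef, np.sort(np.array(support, dtype=int)))


def omp_batch(A: np.ndarray, Y: np.ndarray, T: int) -> np.ndarray:
    """OMP coefficients for every column of ``Y``; returns a K x P matrix."""
    K = A.shape[1]
    out = np.zeros((K, Y.shape[1]))
    for p in range(Y.shape[1]):
        out[:, p] = omp(A, Y[:, p], T).coefficients
    return out


# ---------------------------------------------------------------------------
# SL0
# ---------------------------------------------------------------------------

class _Projector:
    """Least-squares projector onto {x : Ax = y} via Cholesky of AAᵀ."""

    def __init__(self, A: np.ndarray):
        self.A = A
        gram = A @ A.T
        try:
            self._cho = scipy.linalg.cho_factor(gram)
            self._pinv = None
        except scipy.linalg.LinAlgError:
            warnings.warn("rank-deficient system; using pseudo-inverse", stacklevel=3)
            self._cho = None
            self._pinv = np.linalg.pinv(A)

    def min_l2(self, y: np.ndarray) -> np.ndarray:
        if self._cho is not None:
            return self.A.T @ scipy.linalg.cho_solve(self._cho, y)
        return self._pinv @ y

    def project(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return x - self.min_l2(self.A @ x - y)


def sl0(A: np.ndarray, y: np.ndarray, params: SL0Params | None = None) -> np.ndarray:
    """Smoothed-ℓ0 solve of Ax = y (noiseless, equality-constrained).

    ``y`` may be a vector or an (M, P) batch; the return matches its shape.
    The initial σ is ``2 · max|A⁺y|`` per column, annealed by
    ``sigma_decrease`` down to ``sigma_min``.

    With M >= K the constraint set is a single point (or empty), so the
    least-squares solution is returned directly — no sparsification is
    possible; this includes the square-dictionary failure mode.  In the
    underdetermined case a final debias pass refits, by least squares, the
    smallest magnitude-ranked support that reproduces ``y`` exactly; when no
    strictly sparse support is exactly consistent (the generic noisy case)
    the annealed iterate is returned untouched.
    """
    params = params or SL0Params()
    A = np.asarray(A, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    single = y_arr.ndim == 1
    Y = y_arr[:, None] if single else y_arr
    if Y.shape[0] != A.shape[0]:
        raise DimensionError(f"y has {Y.shape[0]} rows, A has {A.shape[0]}")

    m, k = A.shape
    if m >= k:
        X, *_ = scipy.linalg.lstsq(A, Y)
        X = np.atleast_2d(X.T).T
        return X[:, 0] if single else X

    proj = _Projector(A)
    X = proj.min_l2(Y)
    sigma = 2.0 * np.maximum(np.max(np.abs(X), axis=0), params.sigma_min)
    active = sigma > params.sigma_min  # each column anneals independently
    while active.any():
        Xa, Ya, s = X[:, active], Y[:, active], sigma[active]
        for _ in range(params.inner_iterations):
            delta = Xa * np.exp(-(Xa**2) / (2.0 * s**2))
            Xa = Xa - params.mu * delta
            Xa = proj.project(Xa, Ya)
        X[:, active] = Xa
        sigma[active] *= params.sigma_decrease
        active = sigma > params.sigma_min
    X = _debias(A, Y, X)
    return X[:, 0] if single else X


def _debias(
    A: np.ndarray,
    Y: np.ndarray,
    X: np.ndarray,
    residual_tol: float = 1e-9,
    max_support: int = 32,
) -> np.ndarray:
    """Replace each column by the sparsest exactly-consistent magnitude-ranked
    refit, where one exists (escapes shallow local maxima of the smoothed
    objective on exactly sparse instances)."""
    m = A.shape[0]
    limit = min(m - 1, A.shape[1], max_support)
    out = X.copy()
    Q = np.empty((m, limit))
    for p in range(X.shape[1]):
        y = Y[:, p]
        ynorm = np.linalg.norm(y)
        if ynorm == 0.0:
            out[:, p] = 0.0
            continue
        order = np.argsort(-np.abs(X[:, p]))
        # incremental Gram-Schmidt: track the residual of y against the span
        # of the top-ranked columns; solve for coefficients only on success
        resid = y.copy()
        for size in range(1, limit + 1):
            a = A[:, order[size - 1]].copy()
            q = a - Q[:, : size - 1] @ (Q[:, : size - 1].T @ a)
            nq = np.linalg.norm(q)
            if nq > 1e-12 * np.linalg.norm(a):
                q /= nq
                Q[:, size - 1] = q
                resid = resid - q * (q @ resid)
            else:
                Q[:, size - 1] = 0.0
            if np.linalg.norm(resid) < residual_tol * ynorm:
                support = order[:size]
                sol, *_ = scipy.linalg.lstsq(A[:, support], y)
                out[:, p] = 0.0
                out[support, p] = sol
                break
    return out


# ---------------------------------------------------------------------------
# exhaustive oracle (for tests and cross-checks only)
# ---------------------------------------------------------------------------

def l0_oracle(
    A: np.ndarray,
    y: np.ndarray,
    max_support: int,
    residual_tol: float = 1e-9,
) -> SparseCode | None:
    """Sparsest exactly-consistent solution by exhaustive support search.

    Small instances only (K ≤ 20, max_support ≤ 3): supports are enumerated
    by increasing size and the first exact fit wins.  Returns ``None`` when
    no support within budget reproduces ``y``.
    """
    from itertools import combinations

    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    k = A.shape[1]
    if k > 20 or max_support > 3:
        raise BudgetError(f"l0_oracle limited to K <= 20, support <= 3 (got {k}, {max_support})")
    if np.linalg.norm(y) < residual_tol:
        return SparseCode(np.zeros(k), np.array([], dtype=int))
    for size in range(1, max_support + 1):
        for support in combinations(range(k), size):
            As = A[:, support]
            sol, *_ = scipy.linalg.lstsq(As, y)
            if np.linalg.norm(y - As @ sol) < residual_tol:
                coef = np.zeros(k)
                coef[list(support)] = sol
                return SparseCode(coef, np.array(support, dtype=int))
    return None
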