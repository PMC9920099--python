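"""Tensor primitives and parallel factorization (CP/PARAFAC) solvers.

Two factorizations live here:

* :class:`CPDecomposition` — classic least-squares PARAFAC for third-order
  tensors, solved by alternating least squares (ALS) on the mode-n
  matricizations via the Khatri-Rao product.
* :class:`L1NonnegFactorization` — the two-way variant used for group
  connectivity analysis: X (K^2 x S) is approximated by a sum of f
  non-negative rank-one terms a(r) b(r)^T minimizing the *L1* norm of the
  residual, which favours sparse reconstructions of binarized connectivity
  stacks.

The vectorization convention is pinned so that for a third-order tensor
``X = sum_r a(r) o b(r) o c(r)`` the identity
``matricize(X, 1) == A @ khatri_rao(B, C).T`` holds exactly: mode-n
matricization puts the mode-n fibers in columns with the remaining axes
flattened row-major in their original order, and ``khatri_rao(B, C)`` takes
column-wise Kronecker products ``kron(b(r), c(r))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "CPFactors",
    "outer_rank1",
    "khatri_rao",
    "matricize",
    "fold",
    "CPDecomposition",
    "parafac_als",
    "L1NonnegFactorization",
    "l1_nonneg_factorize",
]


@dataclass
class CPFactors:
    """Factor matrices of a CP model plus solver metadata.

    A has shape (I, R); B has shape (J, R); C is present only for the
    three-way case. ``objective_trace`` holds the objective value after each
    outer iteration of the run that produced these factors.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray | None = None
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: np.ndarray | None = None  # boolean mask of all-zero factors

    @property
    def rank(self) -> int:
        return self.A.shape[1]


def outer_rank1(a: np.ndarray, b: np.ndarray, c: np.ndarray | None = None) -> np.ndarray:
    """Rank-one outer product a o b (matrix) or a o b o c (third-order tensor)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if c is None:
        return np.multiply.outer(a, b)
    c = np.asarray(c, dtype=float)
    return np.einsum("i,j,d->ijd", a, b, c)


def khatri_rao(B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product: column r is kron(B[:, r], C[:, r]).

    For B (J x R) and C (D x R) the result has shape (J*D x R), with the
    first factor's index striding slowest — the ordering that matches the
    row-major matricization used throughout this package.
    """
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if B.ndim != 2 or C.ndim != 2:
        raise ValueError("khatri_rao expects two matrices")
    if B.shape[1] != C.shape[1]:
        raise ValueError(
            f"column count mismatch: B has {B.shape[1]} columns, C has {C.shape[1]}"
        )
    J, R = B.shape
    D = C.shape[0]
    # (J, 1, R) * (1, D, R) -> (J, D, R) -> reshape row-major
    return (B[:, None, :] * C[None, :, :]).reshape(J * D, R)


def matricize(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization: mode-n fibers become the columns of the result.

    ``mode`` is 1-based (1, 2 or 3). Remaining axes are flattened row-major
    in their original order, so for a CP tensor
    ``matricize(X, 1) = A @ khatri_rao(B, C).T`` and cyclically for the
    other modes.
    """
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError("matricize expects a third-order tensor")
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    ax = mode - 1
    return np.moveaxis(t, ax, 0).reshape(t.shape[ax], -1)


def fold(mat: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`matricize`: refold a mode-n unfolding into ``shape``."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    ax = mode - 1
    rest = [shape[i] for i in range(3) if i != ax]
    return np.moveaxis(np.asarray(mat).reshape(shape[ax], *rest), 0, ax)


def _ls_update(unfolding: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Solve min_A ||unfolding - A Z^T||_F via the normal equations.

    Falls back to a ridge-regularized pseudoinverse when Z^T Z is
    rank-deficient (degenerate Khatri-Rao product), with a warning.
    """
    G = Z.T @ Z
    rhs = unfolding @ Z
    try:
        return np.linalg.solve(G, rhs.T).T
    except np.linalg.LinAlgError:
        warnings.warn(
            "rank-deficient Khatri-Rao product; using regularized pseudoinverse",
            RuntimeWarning,
            stacklevel=3,
        )
        reg = 1e-10 * max(np.trace(G), 1.0)
        return np.linalg.solve(G + reg * np.eye(G.shape[0]), rhs.T).T


class CPDecomposition(BaseEstimator):
    """Least-squares PARAFAC of a third-order tensor via ALS.

    Parameters
    ----------
    rank : int
        Number R of rank-one components.
    tol : float
        Relative change of the Frobenius objective below which ALS stops.
    max_iter : int
        Maximum number of outer (full A,B,C sweep) iterations.
    n_init : int
        Random restarts; the factors with the best final objective are kept.
    random_state : int or numpy Generator, optional
        Seeds the random initializations.

    Attributes
    ----------
    factors_ : CPFactors
        Fitted factor matrices A, B, C with the objective trace of the
        winning restart.
    objective_ : float
        Final Frobenius-norm objective ||X - X_hat||_F of the best restart.
    """

    def __init__(self, rank=1, tol=1e-8, max_iter=200, n_init=1, random_state=None):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float)
        if t.ndim != 3:
            raise ValueError("CPDecomposition expects a third-order tensor")
        if not np.all(np.isfinite(t)):
            raise ValueError("tensor contains non-finite entries")
        I, J, D = t.shape
        R = int(self.rank)
        if R < 1:
            raise ValueError("rank must be >= 1")
        cap = min(J * D, I * D, I * J)
        if R > cap:
            raise ValueError(f"rank {R} exceeds the identifiable bound {cap}")
        rng = np.random.default_rng(self.random_state)
        unf = [matricize(t, m) for m in (1, 2, 3)]

        best = None
        for _ in range(max(1, int(self.n_init))):
            A = rng.random((I, R))
            B = rng.random((J, R))
            C = rng.random((D, R))
            trace = []
            prev = np.inf
            for _ in range(int(self.max_iter)):
                A = _ls_update(unf[0], khatri_rao(B, C))
                B = _ls_update(unf[1], khatri_rao(A, C))
                C = _ls_update(unf[2], khatri_rao(A, B))
                obj = float(np.linalg.norm(unf[0] - A @ khatri_rao(B, C).T))
                trace.append(obj)
                if prev < np.inf and abs(prev - obj) <= self.tol * max(prev, 1e-30):
                    break
                prev = obj
            if best is None or trace[-1] < best.objective_trace[-1]:
                best = CPFactors(A=A, B=B, C=C, objective_trace=np.asarray(trace))
        self.factors_ = best
        self.objective_ = float(best.objective_trace[-1])
        return self

    def reconstruct(self) -> np.ndarray:
        f = self.factors_
        return np.einsum("ir,jr,dr->ijd", f.A, f.B, f.C)


def parafac_als(t, R, tol=1e-8, max_iter=200, rng_seed=None, n_init=1) -> CPFactors:
    """Functional wrapper over :class:`CPDecomposition`."""
    est = CPDecomposition(rank=R, tol=tol, max_iter=max_iter, n_init=n_init,
                          random_state=rng_seed).fit(t)
    return est.factors_


# ---------------------------------------------------------------------------
# Non-negative L1 two-way factorization
# ---------------------------------------------------------------------------

def _l1_objective(X, A, B):
    return float(np.abs(X - A @ B.T).sum())


class L1NonnegFactorization(BaseEstimator):
    """Sparse non-negative two-way factorization under an L1 loss.

    Approximates a non-negative matrix X (I x S) by ``A @ B.T`` with
    A (I x f) >= 0 and B (S x f) >= 0, minimizing ``sum |X - A B^T|`` —
    the sum of absolute residuals rather than their squares. The L1 loss
    yields sparse reconstructions, which suits stacks of binarized
    connectivity patterns where most cells are exactly zero.

    The solver alternates iteratively-reweighted multiplicative updates of
    A and B: each sweep re-weights entries by ``1/sqrt(r^2 + eps^2)`` with
    the current residuals r (the IRLS surrogate of the absolute loss) and
    applies the Lee-Seung-type multiplicative step for the resulting
    weighted least-squares subproblem, which preserves non-negativity
    without any explicit projection and decreases the weighted surrogate
    monotonically. The loss is non-convex jointly, so ``n_init`` seeded
    random restarts are run and the best final objective kept.

    After convergence every column of A is rescaled to unit L1 norm with the
    scale absorbed into the matching column of B, so subject loadings are
    commensurable across factors. Dead factors — those whose total
    contribution ``||a(r)||_1 * ||b(r)||_1`` is negligible against
    ``||X||_1`` — are flagged in ``degenerate_factors_`` rather than
    dropped; multiplicative updates drive dying factors to zero only
    asymptotically, so the flag is contribution-based, not an exact-zero
    test.

    Parameters
    ----------
    n_components : int
        Number f of rank-one terms; must satisfy f <= S (the rank of an
        I x S matrix with I >= S is at most S).
    tol : float
        Relative objective change below which the outer loop stops.
    max_iter : int
        Maximum outer iterations (one A and one B update each).
    n_init : int
        Seeded random restarts.
    eps : float
        IRLS smoothing added to the residual magnitude in the weights.
    init : {'data', 'random'}
        'data' (default) seeds each pattern column with the column-wise
        mean of X under multiplicative jitter — the data-driven strategy
        standard for NMF (cf. NNDSVD-style initializations). Because the
        updates are multiplicative, rows that are zero in every column of X
        then stay exactly zero, and patterns start at full strength on the
        observed support. 'random' uses i.i.d. uniform(0,1) entries.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    basis_ : ndarray (I, f)
        Non-negative factor patterns, each column unit-L1 (or zero).
    loadings_ : ndarray (S, f)
        Non-negative per-column (e.g. per-subject) weights.
    objective_ : float
        Best final L1 objective across restarts.
    objective_trace_ : ndarray
        Objective after each outer iteration of the winning restart.
    degenerate_factors_ : ndarray of bool, shape (f,)
        True where a factor is identically zero.
    """

    def __init__(self, n_components=2, tol=1e-6, max_iter=500, n_init=5,
                 eps=1e-8, init="data", random_state=None):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.eps = eps
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if np.any(X < 0):
            raise ValueError("X must be non-negative elementwise")
        I, S = X.shape
        f = int(self.n_components)
        if f < 1:
            raise ValueError("n_components must be >= 1")
        if f > S:
            raise ValueError(
                f"n_components={f} exceeds the admissible bound: the number of "
                f"factors cannot exceed the rank of X, hence at most S={S} columns"
            )
        rng = np.random.default_rng(self.random_state)

        if self.init not in ("data", "random"):
            raise ValueError(f"init must be 'data' or 'random', got {self.init!r}")
        col_mean = X.mean(axis=1)
        eps2 = self.eps * self.eps
        best_obj = np.inf
        best = None
        for _ in range(max(1, int(self.n_init))):
            if self.init == "data":
                A = col_mean[:, None] * (1.0 + 0.5 * rng.random((I, f)))
            else:
                A = rng.random((I, f))
            B = rng.random((S, f))
            init_obj = _l1_objective(X, A, B)
            trace = [init_obj]
            prev = init_obj
            for _ in range(int(self.max_iter)):
                R = X - A @ B.T
                W = 1.0 / np.sqrt(R * R + eps2)
                A *= ((W * X) @ B) / ((W * (A @ B.T)) @ B + 1e-12)
                R = X - A @ B.T
                W = 1.0 / np.sqrt(R * R + eps2)
                B *= ((W * X).T @ A) / ((W * (A @ B.T)).T @ A + 1e-12)
                obj = _l1_objective(X, A, B)
                trace.append(obj)
                if abs(prev - obj) <= self.tol * max(prev, 1e-30):
                    break
                prev = obj
            if trace[-1] < best_obj:
                best_obj = trace[-1]
                best = (A, B, np.asarray(trace))

        A, B, trace = best
        A, B, dead = _normalize_columns(A, B, x_norm=float(np.abs(X).sum()))
        self.basis_ = A
        self.loadings_ = B
        self.degenerate_factors_ = dead
        self.objective_ = float(best_obj)
        self.objective_trace_ = trace
        self.n_features_in_ = S
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).basis_

    @property
    def factors_(self) -> CPFactors:
        return CPFactors(A=self.basis_, B=self.loadings_,
                         objective_trace=self.objective_trace_,
                         degenerate=self.degenerate_factors_)


def _normalize_columns(A, B, x_norm=None):
    """Rescale each column of A to unit L1 norm, pushing the scale into B.

    A factor is flagged dead when its total contribution
    ``||a(r)||_1 * ||b(r)||_1`` is zero, or negligible (< 1e-9) relative to
    ``x_norm`` when given; dead factors are zeroed out and reported in the
    returned boolean mask.
    """
    A = A.copy()
    B = B.copy()
    a_norms = np.abs(A).sum(axis=0)
    contrib = a_norms * np.abs(B).sum(axis=0)
    floor = 0.0 if x_norm is None else 1e-9 * x_norm
    dead = contrib <= floor
    live = ~dead
    A[:, live] /= a_norms[live]
    B[:, live] *= a_norms[live]
    A[:, dead] = 0.0
    B[:, dead] = 0.0
    return A, B, dead


def l1_nonneg_factorize(X, f, tol=1e-6, max_iter=500, n_init=5, rng_seed=None) -> CPFactors:
    """Functional wrapper over :class:`L1NonnegFactorization`."""
    est = L1NonnegFactorization(n_components=f, tol=tol, max_iter=max_iter,
                                n_init=n_init, random_state=rng_seed).fit(X)
    return est.factors_
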