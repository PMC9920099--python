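"""Grand-average network extraction from a stack of subject networks.

Pipeline: vectorize each subject's K x K connectivity matrix (row-major)
into a column of X (K^2 x S); factorize X into f non-negative rank-one
terms under an L1 loss; pick the factor whose subject loadings have the
smallest variance — a pattern common to the group should be expressed with
near-equal weight in every subject; reshape that factor back to K x K,
binarize at a small threshold, and re-assign to each surviving connection
the mean of its observed values across the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .decomposition import L1NonnegFactorization

__all__ = [
    "SubjectStack",
    "GrandAverageResult",
    "stack_subjects",
    "unstack",
    "GrandAverageExtractor",
    "extract_grand_average",
    "spatial_filter",
    "degrees",
]


@dataclass
class SubjectStack:
    """K^2 x S matrix whose column s is subject s's vectorized network.

    Vectorization is row-major: entry order pi_11, pi_12, ..., pi_1K,
    pi_21, ..., pi_KK. The admissible number of factors for any
    factorization of X is bounded by S (the rank of a tall K^2 x S matrix).
    """

    X: np.ndarray
    K: int
    subject_ids: list = field(default_factory=list)
    node_labels: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[1]

    @property
    def max_factors(self) -> int:
        return self.n_subjects


def stack_subjects(mats, subject_ids=None, node_labels=None) -> SubjectStack:
    """Stack S non-negative K x K matrices column-wise into X (K^2 x S)."""
    mats = [np.asarray(m, dtype=float) for m in mats]
    if not mats:
        raise ValueError("need at least one subject matrix")
    K = mats[0].shape[0]
    for s, m in enumerate(mats):
        if m.shape != (K, K):
            raise ValueError(
                f"subject {s} has shape {m.shape}, expected ({K}, {K})"
            )
        if np.any(m < 0):
            raise ValueError(f"subject {s} has negative entries")
    X = np.column_stack([m.reshape(-1) for m in mats])  # row-major vec
    if subject_ids is None:
        subject_ids = list(range(len(mats)))
    if node_labels is None:
        node_labels = [f"n{i}" for i in range(K)]
    return SubjectStack(X=X, K=K, subject_ids=list(subject_ids),
                        node_labels=list(node_labels))


def unstack(column: np.ndarray, K: int) -> np.ndarray:
    """Inverse of the row-major vectorization used by :func:`stack_subjects`."""
    return np.asarray(column).reshape(K, K)


@dataclass
class GrandAverageResult:
    binary: np.ndarray
    weighted: np.ndarray
    scores: np.ndarray            # continuous selected-factor weights, K x K
    selected_factor: int
    loading_variances: np.ndarray
    objective: float


class GrandAverageExtractor(BaseEstimator):
    """Extract the group-common network from a subject stack.

    Fits the non-negative L1 factorization with ``n_factors`` components,
    selects the non-degenerate factor whose unit-L1-normalized loading
    column has minimum population variance across subjects (ties broken by
    lower index), reshapes it to K x K and binarizes at ``threshold``.

    Parameters
    ----------
    n_factors : int
        Number of rank-one terms; must not exceed the number of subjects.
    threshold : float
        Binarization cutoff (default 0.001): entries of the selected
        pattern below it are set to 0, the rest to 1.
    threshold_scale : {'max', 'l1', 'raw'}
        Scale on which the cutoff is applied. 'max' (default) rescales the
        pattern to unit maximum first, making the cutoff a relative
        numerical-zero test that is invariant to network size; 'l1' applies
        it to the unit-L1-normalized pattern; 'raw' to the solver's
        unnormalized output.
    tol, max_iter, n_init, random_state
        Passed through to :class:`L1NonnegFactorization`.

    Attributes
    ----------
    binary_ : ndarray (K, K) of 0/1
        The extracted grand-average adjacency matrix.
    weighted_ : ndarray (K, K)
        Mean observed value of each surviving connection across the
        population; zero where ``binary_`` is zero.
    scores_ : ndarray (K, K)
        Continuous selected-factor weights before binarization.
    selected_factor_ : int
    loading_variances_ : ndarray (n_factors,)
        Population variance of each loading column (NaN for degenerate
        factors).
    objective_ : float
    """

    def __init__(self, n_factors=2, threshold=0.001, threshold_scale="max",
                 tol=1e-6, max_iter=500, n_init=5, random_state=None):
        self.n_factors = n_factors
        self.threshold = threshold
        self.threshold_scale = threshold_scale
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        stack = X if isinstance(X, SubjectStack) else stack_subjects(X)
        if not 1 <= self.n_factors <= stack.max_factors:
            raise ValueError(
                f"n_factors={self.n_factors} outside the admissible range "
                f"[1, {stack.max_factors}]: the factor count cannot exceed "
                f"the number of subjects S={stack.n_subjects}"
            )
        fac = L1NonnegFactorization(
            n_components=self.n_factors, tol=self.tol, max_iter=self.max_iter,
            n_init=self.n_init, random_state=self.random_state,
        ).fit(stack.X)

        variances = np.var(fac.loadings_, axis=0)  # population variance
        variances = np.where(fac.degenerate_factors_, np.nan, variances)
        if np.all(np.isnan(variances)):
            raise ValueError("all factors are degenerate (identically zero)")
        selected = int(np.nanargmin(variances))

        # factorization was done on raw X; recover the raw-scale pattern for
        # the 'raw' threshold mode (basis_ columns are unit-L1)
        loading_scale = np.abs(fac.loadings_[:, selected]).sum()
        scores = unstack(fac.basis_[:, selected], stack.K)
        if self.threshold_scale == "max":
            peak = scores.max()
            ref = scores / peak if peak > 0 else scores
        elif self.threshold_scale == "l1":
            ref = scores
        elif self.threshold_scale == "raw":
            ref = scores * loading_scale / max(stack.n_subjects, 1)
        else:
            raise ValueError(
                f"threshold_scale must be 'max', 'l1' or 'raw', "
                f"got {self.threshold_scale!r}"
            )
        binary = (ref >= self.threshold).astype(float)
        mean_net = unstack(stack.X.mean(axis=1), stack.K)
        weighted = np.where(binary == 1, mean_net, 0.0)

        self.stack_ = stack
        self.factorization_ = fac
        self.scores_ = scores
        self.binary_ = binary
        self.weighted_ = weighted
        self.selected_factor_ = selected
        self.loading_variances_ = variances
        self.objective_ = fac.objective_
        return self

    @property
    def result_(self) -> GrandAverageResult:
        return GrandAverageResult(
            binary=self.binary_, weighted=self.weighted_, scores=self.scores_,
            selected_factor=self.selected_factor_,
            loading_variances=self.loading_variances_,
            objective=self.objective_,
        )


def extract_grand_average(stack, f, binarize_threshold=0.001,
                          threshold_scale="max", tol=1e-6, max_iter=500,
                          n_init=5, rng_seed=None) -> GrandAverageResult:
    """Functional wrapper over :class:`GrandAverageExtractor`."""
    est = GrandAverageExtractor(
        n_factors=f, threshold=binarize_threshold,
        threshold_scale=threshold_scale, tol=tol, max_iter=max_iter,
        n_init=n_init, random_state=rng_seed,
    ).fit(stack)
    return est.result_


def spatial_filter(mat: np.ndarray, grid: dict, node_labels: list[str],
                   line_order=(5, 3, 1, 2, 4, 6)) -> np.ndarray:
    """Zero short-distance connections between grid-adjacent electrodes.

    ``grid`` maps electrode name -> (row, line) with rows as montage row
    names (e.g. FC, C, CP, P in anterior-posterior order) or integers, and
    ``line`` the sagittal line number. Two electrodes are adjacent when
    their (row index, line position) coordinates are at Chebyshev distance
    1, where line position is the index of the line in ``line_order``
    (left-to-right on the scalp). Adjacent pairs are zeroed in both
    directions, except pairs with one electrode on line 1 and the other on
    line 2 — these flank the midline, where volume conduction between
    hemispheres is not a concern, and are retained.
    """
    mat = np.asarray(mat, dtype=float).copy()
    K = mat.shape[0]
    if len(node_labels) != K:
        raise ValueError("node_labels length must match matrix size")

    rows = sorted({r for r, _ in grid.values()}, key=str)
    # preserve insertion order of distinct row names if not comparable
    seen: dict = {}
    for r, _ in grid.values():
        seen.setdefault(r, len(seen))
    line_pos = {line: i for i, line in enumerate(line_order)}

    coords = {}
    for name in node_labels:
        if name not in grid:
            raise KeyError(f"electrode {name!r} has no grid coordinate")
        r, line = grid[name]
        if line not in line_pos:
            raise KeyError(f"electrode {name!r} on unknown sagittal line {line}")
        coords[name] = (seen[r], line_pos[line])

    lines = {name: grid[name][1] for name in node_labels}
    for i in range(K):
        for j in range(i + 1, K):
            (ri, ci), (rj, cj) = coords[node_labels[i]], coords[node_labels[j]]
            if max(abs(ri - rj), abs(ci - cj)) == 1:
                if {lines[node_labels[i]], lines[node_labels[j]]} == {1, 2}:
                    continue  # midline-flanking pair retained
                mat[i, j] = 0.0
                mat[j, i] = 0.0
    return mat


def degrees(mat: np.ndarray, node_labels=None):
    """Per-node in-, out- and total degree of a binary directed network.

    Cell (i, j) encodes the influence j -> i, so the in-degree of node v is
    its row sum and the out-degree its column sum; deg(v) = id(v) + od(v).
    Returns a pandas DataFrame indexed by node label.
    """
    import pandas as pd

    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.all(np.isin(mat, (0, 1))):
        raise ValueError("degree computation requires a binary matrix")
    if np.any(np.diag(mat) != 0):
        raise ValueError("diagonal must be zero (no self-loops)")
    indeg = mat.sum(axis=1).astype(int)
    outdeg = mat.sum(axis=0).astype(int)
    if node_labels is None:
        node_labels = [f"n{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(
        {"in_degree": indeg, "out_degree": outdeg, "degree": indeg + outdeg},
        index=list(node_labels),
    )
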