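"""Synthetic benchmark networks: a ground-truth directed graph plus
per-subject variants with a fraction of connections displaced.

The generator emulates a group connectivity study: every subject shares a
common binary directed network (the grand average) except that a fraction
``m`` of its edges is swapped to new positions, modelling inter-subject
variability. Swaps preserve the edge count, so every subject network has
exactly the same density as the ground truth. Self-loops are excluded
throughout: density counts the K*(K-1) off-diagonal cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "generate_ground_truth",
    "perturb_subject",
    "generate_dataset",
]


@dataclass
class GroundTruth:
    matrix: np.ndarray        # K x K binary, zero diagonal
    density: float
    edge_count: int

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SyntheticDataset:
    ground_truth: GroundTruth
    subjects: list[np.ndarray]   # S binary K x K matrices
    swap_fraction: float
    seed: int | None


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _offdiag_indices(K: int) -> np.ndarray:
    """Flat indices of the K*(K-1) off-diagonal cells of a K x K matrix."""
    idx = np.arange(K * K)
    return idx[idx // K != idx % K]


def generate_ground_truth(K: int, density: float = 0.1, rng_seed=None) -> GroundTruth:
    """Sample a binary directed network with a fixed number of edges.

    Exactly ``round(density * K * (K-1))`` distinct off-diagonal cells are
    set to 1, chosen uniformly without replacement; the diagonal stays zero.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    edge_count = _round_half_away(density * K * (K - 1))
    if edge_count == 0:
        raise ValueError(f"density {density} yields zero edges at K={K}")
    rng = np.random.default_rng(rng_seed)
    cells = _offdiag_indices(K)
    chosen = rng.choice(cells, size=edge_count, replace=False)
    mat = np.zeros(K * K)
    mat[chosen] = 1.0
    return GroundTruth(matrix=mat.reshape(K, K), density=density, edge_count=edge_count)


def perturb_subject(gt: GroundTruth, m: float, rng_seed=None) -> np.ndarray:
    """Displace a fraction ``m`` of the ground-truth edges to empty cells.

    ``round(m * edge_count)`` existing edges, chosen uniformly, are removed
    and the same number of new edges placed uniformly among the empty
    off-diagonal cells, so the subject network keeps exactly the
    ground-truth edge count.
    """
    if not 0 <= m <= 1:
        raise ValueError("swap fraction m must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    K = gt.n_nodes
    flat = gt.matrix.reshape(-1)
    n_swap = _round_half_away(m * gt.edge_count)
    if n_swap == 0:
        return gt.matrix.copy()
    offdiag = _offdiag_indices(K)
    edges = offdiag[flat[offdiag] == 1]
    holes = offdiag[flat[offdiag] == 0]
    if len(holes) < n_swap:
        raise ValueError(
            f"cannot place {n_swap} swapped edges: only {len(holes)} empty cells"
        )
    removed = rng.choice(edges, size=n_swap, replace=False)
    added = rng.choice(holes, size=n_swap, replace=False)
    out = flat.copy()
    out[removed] = 0.0
    out[added] = 1.0
    return out.reshape(K, K)


def generate_dataset(K: int, S: int, m: float, density: float = 0.1,
                     rng_seed=None) -> SyntheticDataset:
    """One fresh ground truth plus S independently perturbed subjects.

    Per-subject RNG streams are spawned deterministically from the dataset
    seed, so the dataset is fully reproducible and subjects independent.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    gt_seed, *subj_seeds = ss.spawn(S + 1)
    gt = generate_ground_truth(K, density, rng_seed=gt_seed)
    subjects = [perturb_subject(gt, m, rng_seed=s) for s in subj_seeds]
    return SyntheticDataset(ground_truth=gt, subjects=subjects,
                            swap_fraction=m, seed=rng_seed)
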