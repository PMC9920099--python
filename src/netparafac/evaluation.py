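"""Scoring of recovered networks against ground truth, and the Monte-Carlo
simulation harness over (nodes, subjects, swap fraction, factors) grids.

All counts and rates are computed over the off-diagonal cells only:
self-connections are excluded from the network model throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .grand_average import extract_grand_average, stack_subjects
from .synthetic import generate_dataset

__all__ = [
    "Confusion",
    "confusion",
    "fpr",
    "fnr",
    "auc",
    "run_simulation",
    "score_extraction",
]


@dataclass
class Confusion:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _offdiag_mask(K: int) -> np.ndarray:
    return ~np.eye(K, dtype=bool)


def confusion(est: np.ndarray, gt: np.ndarray) -> Confusion:
    """Confusion counts of an estimated binary network vs ground truth."""
    est = np.asarray(est)
    gt = np.asarray(gt)
    if est.shape != gt.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {gt.shape}")
    m = _offdiag_mask(est.shape[0])
    e = est[m].astype(bool)
    g = gt[m].astype(bool)
    return Confusion(
        TP=int(np.sum(e & g)),
        FP=int(np.sum(e & ~g)),
        FN=int(np.sum(~e & g)),
        TN=int(np.sum(~e & ~g)),
    )


def fpr(c: Confusion) -> float:
    """False-positive rate FP / (FP + TN)."""
    denom = c.FP + c.TN
    if denom == 0:
        raise ZeroDivisionError("FPR undefined: FP + TN is zero")
    return c.FP / denom


def fnr(c: Confusion) -> float:
    """False-negative rate FN / (TP + FN)."""
    denom = c.TP + c.FN
    if denom == 0:
        raise ZeroDivisionError("FNR undefined: TP + FN is zero")
    return c.FN / denom


def auc(scores: np.ndarray, gt: np.ndarray) -> float:
    """ROC area of continuous scores against binary ground truth.

    Mann-Whitney formulation over the off-diagonal cells; ties contribute
    one half. Requires at least one edge and one non-edge in the truth.
    """
    scores = np.asarray(scores, dtype=float)
    gt = np.asarray(gt)
    if scores.shape != gt.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {gt.shape}")
    m = _offdiag_mask(gt.shape[0])
    y = gt[m].astype(int)
    if y.min() == y.max():
        raise ValueError("ground truth must contain both edges and non-edges")
    return float(roc_auc_score(y, scores[m]))


def score_extraction(result, gt_matrix: np.ndarray) -> dict:
    """FPR, FNR and AUC of one grand-average extraction vs its ground truth.

    FPR/FNR use the binarized network; AUC uses the continuous selected-
    factor weights before binarization.
    """
    c = confusion(result.binary, gt_matrix)
    return {"FPR": fpr(c), "FNR": fnr(c), "AUC": auc(result.scores, gt_matrix)}


def run_simulation(grid: dict, T: int = 100, seed=None, density: float = 0.1,
                   n_init: int = 5, tol: float = 1e-6, max_iter: int = 500,
                   progress: bool = False) -> pd.DataFrame:
    """Monte-Carlo study of grand-average recovery over a parameter grid.

    For every cell (K, S, m, f) of ``grid`` (keys "K", "S", "m", "f", each
    a list) and every iteration: draw a fresh ground truth and S perturbed
    subjects, run the f-factor extraction, and score it. Iterations are
    independent given their derived seeds, so results do not depend on
    execution order. A failed extraction yields a flagged row, not a crash.

    Returns a long-format DataFrame with columns
    iteration, K, S, m, f, seed, FPR, FNR, AUC, status.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    cells = list(product(grid["K"], grid["S"], grid["m"], grid["f"]))
    root = np.random.SeedSequence(seed)
    rows = []
    iterator = enumerate(cells)
    if progress:
        try:
            from tqdm import tqdm
            iterator = enumerate(tqdm(cells, desc="grid cells"))
        except ImportError:
            pass
    for ci, (K, S, m, f) in iterator:
        for t in range(T):
            child = np.random.SeedSequence(entropy=root.entropy or 0,
                                           spawn_key=(ci, t))
            data_seed, solver_seed = child.spawn(2)
            rec = {"iteration": t, "K": K, "S": S, "m": m, "f": f,
                   "seed": int(data_seed.generate_state(1)[0] % (2**31))}
            try:
                ds = generate_dataset(K, S, m, density=density, rng_seed=data_seed)
                stack = stack_subjects(ds.subjects)
                res = extract_grand_average(
                    stack, f, tol=tol, max_iter=max_iter, n_init=n_init,
                    rng_seed=solver_seed,
                )
                rec.update(score_extraction(res, ds.ground_truth.matrix))
                rec["status"] = "ok"
            except Exception as exc:  # noqa: BLE001 — flagged, not fatal
                rec.update({"FPR": np.nan, "FNR": np.nan, "AUC": np.nan,
                            "status": f"failed: {exc}"})
            rows.append(rec)
    return pd.DataFrame(
        rows, columns=["iteration", "K", "S", "m", "f", "seed",
                       "FPR", "FNR", "AUC", "status"],
    )
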