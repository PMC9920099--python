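"""File I/O: labelled connectivity matrices as CSV, epochs as CSV,
electrode-montage layouts as JSON, and run configuration.

CSV dialect: comma separator, '.' decimal, UTF-8, with a header row and an
index column mandatory for matrices. Floats are written with 17 significant
digits so write -> read round-trips are lossless at double precision.
Matrix convention throughout: cell (row i, column j) is the influence
j -> i.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_epochs_csv",
    "load_montage",
    "default_montage",
    "RunConfig",
]


def write_matrix_csv(mat: np.ndarray, path, labels=None) -> None:
    """Write a square labelled matrix; cell (i, j) = influence j -> i."""
    mat = np.asarray(mat)
    if labels is None:
        labels = [f"n{i}" for i in range(mat.shape[0])]
    df = pd.DataFrame(mat, index=labels, columns=labels)
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled numeric matrix; returns (values, labels).

    Ragged rows or non-numeric cells raise with the offending location.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(",")
    ncol = len(header)
    labels, rows = [], []
    for r, ln in enumerate(lines[1:], start=1):
        cells = ln.split(",")
        if len(cells) != ncol:
            raise ValueError(
                f"{path}: ragged row {r}: {len(cells)} fields, expected {ncol}"
            )
        labels.append(cells[0])
        vals = []
        for c, cell in enumerate(cells[1:], start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
        rows.append(vals)
    return np.asarray(rows), labels


def read_epochs_csv(paths, fs: float):
    """Read trial CSVs (rows = samples, columns = channels) into epochs.

    ``paths`` is one path or a list of per-trial paths; all trials must
    share channel names and length. A single CSV containing a ``trial``
    column is split into trials by that column. Returns an
    :class:`~netparafac.mvar.Epochs`.
    """
    from .mvar import Epochs

    if isinstance(paths, (str, Path)):
        paths = [paths]
    trials, channels = [], None
    for p in paths:
        df = pd.read_csv(p)
        if "trial" in df.columns:
            for _, part in df.groupby("trial", sort=True):
                sub = part.drop(columns="trial")
                if channels is None:
                    channels = list(sub.columns)
                trials.append(sub.to_numpy(dtype=float).T)
            continue
        if channels is None:
            channels = list(df.columns)
        elif list(df.columns) != channels:
            raise ValueError(f"{p}: channel names differ from first trial")
        trials.append(df.to_numpy(dtype=float).T)  # K x T
    lengths = {t.shape[1] for t in trials}
    if len(lengths) > 1:
        raise ValueError(f"trials have unequal lengths: {sorted(lengths)}")
    data = np.stack(trials, axis=2)
    ep = Epochs(data=data, fs=fs)
    ep.channels = channels
    return ep


def load_montage(path) -> dict:
    """Load an electrode layout: JSON mapping name -> [row, line].

    Duplicate coordinates raise, as does an empty layout.
    """
    def _no_dupes(pairs):
        names = [k for k, _ in pairs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate electrode names: {sorted(dupes)}")
        return dict(pairs)

    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh, object_pairs_hook=_no_dupes)
    if not raw:
        raise ValueError(f"{path}: empty montage")
    grid = {}
    seen = {}
    for name, coord in raw.items():
        if len(coord) != 2:
            raise ValueError(f"{path}: electrode {name!r} needs [row, line]")
        key = (str(coord[0]), int(coord[1]))
        if key in seen:
            raise ValueError(
                f"{path}: electrodes {seen[key]!r} and {name!r} share "
                f"coordinate {key}"
            )
        seen[key] = name
        grid[name] = (coord[0], int(coord[1]))
    return grid


def default_montage() -> dict:
    """The built-in 24-electrode sensorimotor montage.

    Four anterior-posterior rows (FC, C, CP, P) by six sagittal lines
    (5, 3, 1, 2, 4, 6 from left to right); lines 1 and 2 flank the midline.
    """
    ref = resources.files("netparafac").joinpath(
        "data/montage_sensorimotor24.json"
    )
    with resources.as_file(ref) as p:
        return load_montage(p)


@dataclass
class RunConfig:
    """Simulation-study configuration; round-trips losslessly through JSON."""

    K: list = field(default_factory=lambda: [20])
    S: list = field(default_factory=lambda: [10, 20, 30, 50, 100])
    m: list = field(default_factory=lambda: [0.1, 0.3, 0.5])
    f: list = field(default_factory=lambda: [2, 5, 10])
    T: int = 100
    density: float = 0.1
    seed: int = 0
    threshold: float = 0.001
    threshold_scale: str = "max"
    tol: float = 1e-6
    max_iter: int = 500
    n_init: int = 5

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        unknown = set(raw) - {f.name for f in
                              cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
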