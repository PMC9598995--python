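"""Sliding-window residue datasets, class-balance accounting, class weights.

A protein of length L yields exactly L windows of ``width`` (default 31)
consecutive residue feature rows; the window for residue i is centred on i
(position 16 of 31) and out-of-range positions are zero-padded, so chain
termini are predicted like any other residue.  Splits are by whole protein,
never by residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ResidueFeatureSet
from .structio import ValidationError

__all__ = [
    "WindowDataset",
    "DatasetStats",
    "make_windows",
    "build_window_dataset",
    "dataset_stats",
    "stats_table",
    "class_weights",
    "read_labels",
    "write_labels",
]

#: per-task loss-weight ratios for (binding, non-binding) residues:
#: 10:1 for protein–protein interaction sites, 3:1 for metal binding sites.
TASK_CLASS_WEIGHTS = {
    "ppi": {1: 10.0, 0: 1.0},
    "metal": {1: 3.0, 0: 1.0},
}


@dataclass
class WindowDataset:
    """N fixed-width windows with central-residue labels and group ids."""

    windows: np.ndarray            # N × width × D
    labels: np.ndarray             # N, in {0, 1}
    groups: np.ndarray             # N protein ids (one per window)
    class_weights: dict[int, float]
    block_slices: dict[str, tuple[int, int]]  # column layout of D

    def __post_init__(self) -> None:
        if self.windows.ndim != 3:
            raise ValidationError("windows must be N × width × D")
        n = self.windows.shape[0]
        if not (len(self.labels) == len(self.groups) == n):
            raise ValidationError("windows/labels/groups lengths differ")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def width(self) -> int:
        return self.windows.shape[1]

    @property
    def sample_weights(self) -> np.ndarray:
        w = np.asarray([self.class_weights[int(y)] for y in self.labels])
        return w


def make_windows(X: np.ndarray, width: int = 31) -> np.ndarray:
    """Extract one zero-padded window per residue from an L×D feature matrix.

    Window i (0-based) covers rows i-(width-1)/2 .. i+(width-1)/2; rows
    outside [0, L) are all-zero, so the centre of window i is always
    residue i and the output has exactly L windows.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError(f"window width must be odd and positive, got {width}")
    X = np.asarray(X, dtype=float)
    L, D = X.shape
    half = width // 2
    padded = np.zeros((L + 2 * half, D))
    padded[half:half + L] = X
    idx = np.arange(width)[None, :] + np.arange(L)[:, None]
    return padded[idx]


def build_window_dataset(
    proteins: list[tuple[ResidueFeatureSet, str]],
    blocks: tuple[str, ...],
    width: int = 31,
    class_weights: dict[int, float] | None = None,
) -> WindowDataset:
    """Assemble a WindowDataset from per-protein features and label strings.

    ``proteins`` pairs each feature set with its same-length 0/1 label
    string; windows never mix rows from two proteins.
    """
    all_windows, all_labels, all_groups = [], [], []
    slices = None
    for fset, labels in proteins:
        if len(labels) != len(fset):
            raise ValidationError(
                f"{fset.protein_id}: {len(labels)} labels for "
                f"{len(fset)} residues"
            )
        if not set(labels) <= {"0", "1"}:
            raise ValidationError(
                f"{fset.protein_id}: labels must be a 0/1 string"
            )
        X, sl = fset.concat(blocks)
        if slices is None:
            slices = sl
        elif sl != slices:
            raise ValidationError("inconsistent block layouts across proteins")
        all_windows.append(make_windows(X, width))
        all_labels.append(np.fromiter((int(c) for c in labels), dtype=int))
        all_groups.append(np.full(len(fset), fset.protein_id, dtype=object))
    return WindowDataset(
        windows=np.concatenate(all_windows),
        labels=np.concatenate(all_labels),
        groups=np.concatenate(all_groups),
        class_weights=class_weights or {0: 1.0, 1: 1.0},
        block_slices=slices,
    )


@dataclass(frozen=True)
class DatasetStats:
    """Integer class-balance accounting for one split of labelled proteins."""

    n_proteins: int
    n_residues: int
    n_binding: int

    @property
    def n_nonbinding(self) -> int:
        return self.n_residues - self.n_binding

    @property
    def pct_binding(self) -> float:
        """Percent of binding residues out of all residues."""
        return 100.0 * self.n_binding / self.n_residues

    def __add__(self, other: "DatasetStats") -> "DatasetStats":
        return DatasetStats(
            self.n_proteins + other.n_proteins,
            self.n_residues + other.n_residues,
            self.n_binding + other.n_binding,
        )


def dataset_stats(labels: list[str]) -> DatasetStats:
    """Count proteins, residues and binding residues over label strings."""
    return DatasetStats(
        n_proteins=len(labels),
        n_residues=sum(len(s) for s in labels),
        n_binding=sum(s.count("1") for s in labels),
    )


def stats_table(splits: dict[str, list[str]]) -> pd.DataFrame:
    """Per-split class-balance table with a Total row.

    Columns: Proteins, Total, Binding, Non-Binding, ``% Binding out of
    Total`` (to 4 decimals).
    """
    rows = {}
    total = DatasetStats(0, 0, 0)
    for name, labels in splits.items():
        st = dataset_stats(labels)
        total = total + st
        rows[name] = st
    rows["Total"] = total
    return pd.DataFrame({
        "Proteins": {k: v.n_proteins for k, v in rows.items()},
        "Total": {k: v.n_residues for k, v in rows.items()},
        "Binding": {k: v.n_binding for k, v in rows.items()},
        "Non-Binding": {k: v.n_nonbinding for k, v in rows.items()},
        "% Binding out of Total": {
            k: round(v.pct_binding, 4) for k, v in rows.items()
        },
    })


def class_weights(task: str | None = None,
                  override: dict[int, float] | None = None
                  ) -> dict[int, float]:
    """Loss weights for (binding, non-binding) residues.

    ``ppi`` → {1: 10, 0: 1}; ``metal`` → {1: 3, 0: 1}; an explicit
    ``override`` map is honoured verbatim.
    """
    if override is not None:
        return {int(k): float(v) for k, v in override.items()}
    if task not in TASK_CLASS_WEIGHTS:
        raise ValueError(
            f"unknown task {task!r}; expected one of "
            f"{sorted(TASK_CLASS_WEIGHTS)} or an override map"
        )
    return dict(TASK_CLASS_WEIGHTS[task])


# --------------------------------------------------------------------------
# label files: one line per protein — id, sequence, 0/1 string
# --------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a label file mapping protein id → (sequence, 0/1 label string)."""
    out: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValidationError(f"{path}:{lineno}: expected 'id seq labels'")
        pid, seq, lab = parts
        if len(seq) != len(lab) or not set(lab) <= {"0", "1"}:
            raise ValidationError(
                f"{path}:{lineno}: labels must be a 0/1 string matching "
                "the sequence length"
            )
        out[pid] = (seq, lab)
    return out


def write_labels(entries: dict[str, tuple[str, str]], path: str | Path) -> None:
    lines = [f"{pid} {seq} {lab}" for pid, (seq, lab) in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")
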