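"""Per-residue feature encodings of predicted 3D structure.

Five encodings turn a predicted structure (plus an HHblits conservation
profile and DSSP output) into fixed-width per-residue feature blocks:

``onehot``         L×20   amino-acid identity
``hhblits``        L×30   the conservation profile as given
``space_hhblits``  L×30   spatial filtering: each residue's profile row is
                          replaced by the mean over all residues whose Cα
                          lies within a radius r of its own Cα (closed ball,
                          so r = 0 is exactly "no filtering")
``svd``            L×k    the Cα distance map A projected on its top-k
                          right-singular vectors, A' = A·V_k
``ss``             L×3    3-state secondary structure, one-hot over (H, E, C)
                          after merging the 8 DSSP states
``rasa``           L×1    relative accessible surface area ASA/MaxASA ∈ [0, 1]

Residue indices at the public boundary are 1-based; array rows 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import AA_INDEX, AMINO_ACIDS, MAX_ASA_THEORETICAL
from .structio import (
    ConservationProfile,
    DsspRecord,
    ProteinStructure,
    ValidationError,
    validate_paired,
)

__all__ = [
    "DistanceMap",
    "ResidueFeatureSet",
    "distance_map",
    "neighborhood",
    "spatial_filter",
    "svd_reduce",
    "merge_ss",
    "ss_onehot",
    "rasa",
    "onehot",
    "FeatureEncoder",
]

SS_CLASSES = ("H", "E", "C")


@dataclass
class DistanceMap:
    """L×L symmetric matrix of pairwise Euclidean Cα distances in Å."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"{self.protein_id}: distance map not square")
        if not np.allclose(m, m.T) or np.any(m < 0) or np.any(np.diag(m) != 0):
            raise ValidationError(
                f"{self.protein_id}: not a valid distance matrix"
            )
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def diameter(self) -> float:
        return float(self.matrix.max())


def distance_map(structure: ProteinStructure) -> DistanceMap:
    """Pairwise Euclidean distances between Cα atoms."""
    xyz = structure.ca_coords
    return DistanceMap(structure.protein_id, cdist(xyz, xyz))


def neighborhood(dmap: DistanceMap, i: int, radius: float) -> np.ndarray:
    """1-based indices of all residues within ``radius`` Å of residue ``i``.

    Membership uses the closed ball (distance ≤ radius), so the set always
    contains ``i`` itself and radius 0 keeps only ``i`` — the "no filtering"
    baseline.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if not 1 <= i <= len(dmap):
        raise IndexError(f"residue index {i} out of range 1..{len(dmap)}")
    return np.flatnonzero(dmap.matrix[i - 1] <= radius) + 1


def spatial_filter(profile: ConservationProfile | np.ndarray,
                   dmap: DistanceMap, radius: float) -> np.ndarray:
    """Replace each profile row by the mean over its spatial neighborhood.

    Row i of the result is the arithmetic column-wise mean of the profile
    rows of all residues within ``radius`` Å of residue i (closed ball,
    including i itself).  With radius 0 the input is returned unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    P = profile.matrix if isinstance(profile, ConservationProfile) else \
        np.asarray(profile, dtype=float)
    if P.shape[0] != len(dmap):
        raise ValidationError(
            f"profile has {P.shape[0]} rows but distance map {len(dmap)}"
        )
    mask = dmap.matrix <= radius
    counts = mask.sum(axis=1, keepdims=True)
    return (mask @ P) / counts


def svd_reduce(dmap: DistanceMap, k: int,
               return_spectrum: bool = False):
    """Project the distance map on its top-k right-singular vectors.

    With A = UΣVᵀ (singular values in descending order), returns
    A' = A·V_k, an L×k embedding of the L×L map.  Singular-vector signs are
    made deterministic by forcing the largest-magnitude entry of each
    selected right-singular vector to be positive.
    """
    if not 1 <= k <= len(dmap):
        raise ValueError(f"k must be in 1..{len(dmap)}, got {k}")
    A = dmap.matrix
    _, s, vt = np.linalg.svd(A)
    V = vt.T[:, :k].copy()
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V *= flip
    out = A @ V
    if return_spectrum:
        return out, s
    return out


def merge_ss(ss_code: str) -> str:
    """Collapse the 8-state DSSP alphabet to 3 states.

    H, G, I → H (helix); B, E → E (strand); T and everything else
    (S, P, blank, unknown) → C (coil).  Total on any single character.
    """
    if ss_code in ("H", "G", "I"):
        return "H"
    if ss_code in ("B", "E"):
        return "E"
    return "C"


def ss_onehot(records: list[DsspRecord]) -> np.ndarray:
    """L×3 one-hot encoding over (H, E, C) of merged secondary structure."""
    out = np.zeros((len(records), 3))
    for i, rec in enumerate(records):
        out[i, SS_CLASSES.index(merge_ss(rec.ss_code))] = 1.0
    return out


def rasa(asa: float, aa: str,
         max_asa: dict[str, float] = MAX_ASA_THEORETICAL) -> float:
    """Relative accessible surface area, ASA/MaxASA clipped to [0, 1].

    MaxASA defaults to the theoretical per-residue maxima (Tien et al. 2013);
    observed ASA can exceed the theoretical bound, hence the clip.
    """
    if aa not in max_asa:
        raise KeyError(f"no MaxASA value for residue type {aa!r}")
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    return min(asa / max_asa[aa], 1.0)


def onehot(sequence: str) -> np.ndarray:
    """L×20 one-hot amino-acid encoding.

    Non-standard codes (X, U, B, Z, ...) map to an all-zero row with a
    warning — the least-information encoding.
    """
    out = np.zeros((len(sequence), 20))
    unknown = []
    for i, aa in enumerate(sequence):
        j = AA_INDEX.get(aa)
        if j is None:
            unknown.append(aa)
        else:
            out[i, j] = 1.0
    if unknown:
        warnings.warn(
            f"{len(unknown)} non-standard residue code(s) "
            f"{sorted(set(unknown))} encoded as zero rows", stacklevel=2
        )
    return out


# --------------------------------------------------------------------------
# feature set container and encoder
# --------------------------------------------------------------------------

@dataclass
class ResidueFeatureSet:
    """Named per-residue feature blocks for one protein.

    All blocks share the row count L; ``metadata`` records the filter
    radius (Å) and SVD dimension k used to compute them.
    """

    protein_id: str
    blocks: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {name: b.shape[0] for name, b in self.blocks.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(
                f"{self.protein_id}: blocks disagree in length: {lengths}"
            )

    def __len__(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    @property
    def block_widths(self) -> dict[str, int]:
        return {name: b.shape[1] for name, b in self.blocks.items()}

    def concat(self, names: tuple[str, ...] | list[str]
               ) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
        """Column-concatenate the selected blocks.

        Returns the L×D matrix and a map block name → (start, stop) column
        range, used by the model to route columns to branches.
        """
        missing = [n for n in names if n not in self.blocks]
        if missing:
            raise KeyError(
                f"{self.protein_id}: blocks {missing} not computed "
                f"(have {sorted(self.blocks)})"
            )
        slices = {}
        start = 0
        parts = []
        for n in names:
            b = self.blocks[n]
            slices[n] = (start, start + b.shape[1])
            start += b.shape[1]
            parts.append(b)
        return np.concatenate(parts, axis=1), slices

    def column_names(self, names: tuple[str, ...] | list[str]) -> list[str]:
        cols = []
        for n in names:
            w = self.blocks[n].shape[1]
            if n == "onehot":
                cols += [f"onehot_{a}" for a in AMINO_ACIDS]
            elif n == "ss":
                cols += [f"ss_{c}" for c in SS_CLASSES]
            elif w == 1:
                cols += [n]
            else:
                cols += [f"{n}_{j + 1}" for j in range(w)]
        return cols

    def to_tsv(self, path: str | Path,
               names: tuple[str, ...] | list[str] | None = None) -> None:
        """Export selected blocks as a TSV table, one row per residue."""
        names = list(names) if names is not None else sorted(self.blocks)
        X, _ = self.concat(names)
        df = pd.DataFrame(X, columns=self.column_names(names))
        df.insert(0, "residue", np.arange(1, len(self) + 1))
        df.to_csv(path, sep="\t", index=False)


class FeatureEncoder:
    """Configured computation of per-residue feature blocks for one protein.

    Parameters
    ----------
    radius : float
        Spatial-filter radius in Å for the ``space_hhblits`` block; 0 means
        no filtering (the block then equals the raw profile).
    k : int
        Embedding dimension for the ``svd`` block (8 and 16 are the
        evaluated settings; any 1 ≤ k ≤ L is accepted).
    blocks : tuple of str
        Which blocks to compute.  ``ss`` and ``rasa`` need DSSP records.
    max_asa : dict
        MaxASA normalisation table override.
    """

    ALL_BLOCKS = ("onehot", "hhblits", "space_hhblits", "svd", "ss", "rasa")

    def __init__(self, radius: float = 7.0, k: int = 8,
                 blocks: tuple[str, ...] = ALL_BLOCKS,
                 max_asa: dict[str, float] = MAX_ASA_THEORETICAL):
        unknown = set(blocks) - set(self.ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        self.radius = radius
        self.k = k
        self.blocks = tuple(blocks)
        self.max_asa = max_asa

    def encode(self, structure: ProteinStructure,
               profile: ConservationProfile | None = None,
               dssp_records: list[DsspRecord] | None = None
               ) -> ResidueFeatureSet:
        """Compute the configured blocks; validates paired lengths first."""
        validate_paired(structure, profile, dssp_records)
        need = set(self.blocks)
        if need & {"hhblits", "space_hhblits"} and profile is None:
            raise ValidationError("profile required for HHblits blocks")
        if need & {"ss", "rasa"} and dssp_records is None:
            raise ValidationError("DSSP records required for ss/rasa blocks")

        dmap = None
        if need & {"space_hhblits", "svd"}:
            dmap = distance_map(structure)

        out: dict[str, np.ndarray] = {}
        if "onehot" in need:
            out["onehot"] = onehot(structure.sequence)
        if "hhblits" in need:
            out["hhblits"] = profile.matrix.copy()
        if "space_hhblits" in need:
            out["space_hhblits"] = spatial_filter(profile, dmap, self.radius)
        if "svd" in need:
            out["svd"] = svd_reduce(dmap, min(self.k, len(structure)))
        if "ss" in need:
            out["ss"] = ss_onehot(dssp_records)
        if "rasa" in need:
            out["rasa"] = np.array([
                [rasa(rec.asa, res.aa, self.max_asa)]
                for res, rec in zip(structure.residues, dssp_records)
            ])
        return ResidueFeatureSet(
            structure.protein_id, out,
            metadata={"radius": self.radius, "k": self.k},
        )
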