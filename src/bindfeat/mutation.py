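"""Wild-type vs. mutant change-rate analysis.

For a point substitution, the structural shift predicted for the mutant is
quantified as an element-wise relative change rate

    R = (mutated − original) / original

applied to (a) the raw HHblits profile, (b) the spatially filtered profile,
and (c) each residue's Euclidean distance to the mutated site.  Cells whose
original value is exactly zero are masked (the rate is undefined there),
never silently dropped or set to infinity, so heatmap scaling stays finite.

The spatial filtering used here is a *sequential* variant: neighbors are
visited in ascending distance order and the running value is replaced by
the pairwise mean of itself and the new neighbor after each step.  Later
(nearer-first ordering means more distant) neighbors therefore carry more
weight than in the plain neighborhood mean, amplifying the smoothing; the
plain mean remains the default everywhere else.  Both variants are
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import DistanceMap, distance_map, spatial_filter
from .structio import ConservationProfile, ProteinStructure, ValidationError

__all__ = [
    "MutationDelta",
    "change_rate",
    "sequential_spatial_filter",
    "distance_change_to_site",
    "clip_window",
    "compute_mutation_delta",
]


def change_rate(original: np.ndarray, mutated: np.ndarray) -> np.ma.MaskedArray:
    """Element-wise relative change (mutated − original)/original.

    Returns a masked array: cells with ``original == 0`` are masked
    (undefined rate) and excluded from downstream scaling.
    """
    orig = np.asarray(original, dtype=float)
    mut = np.asarray(mutated, dtype=float)
    if orig.shape != mut.shape:
        raise ValidationError(
            f"shape mismatch: {orig.shape} vs {mut.shape}"
        )
    mask = orig == 0
    safe = np.where(mask, 1.0, orig)
    return np.ma.MaskedArray((mut - orig) / safe, mask=mask)


def sequential_spatial_filter(profile: ConservationProfile | np.ndarray,
                              dmap: DistanceMap, radius: float,
                              mode: str = "pairwise") -> np.ndarray:
    """Running-mean spatial filtering, neighbors added nearest-first.

    For each residue the output row starts as its own profile row; each
    neighbor within ``radius`` (ascending distance, ties broken by residue
    index) then replaces the running row:

    * ``mode="pairwise"`` — by the pairwise mean (running + neighbor)/2,
      the smoothing-amplified variant;
    * ``mode="cumulative"`` — by the cumulative mean over all rows seen so
      far, which is identical to the plain neighborhood mean.

    With exactly one neighbor both modes equal the plain mean.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if mode not in ("pairwise", "cumulative"):
        raise ValueError(f"unknown mode {mode!r}")
    P = profile.matrix if isinstance(profile, ConservationProfile) else \
        np.asarray(profile, dtype=float)
    if P.shape[0] != len(dmap):
        raise ValidationError("profile rows must match distance-map size")
    D = dmap.matrix
    out = np.empty_like(P)
    L = P.shape[0]
    for i in range(L):
        others = np.array([j for j in range(L) if j != i])
        within = others[D[i, others] <= radius] if L > 1 else others[:0]
        order = within[np.lexsort((within, D[i, within]))]
        running = P[i].astype(float).copy()
        for step, j in enumerate(order, start=1):
            if mode == "pairwise":
                running = (running + P[j]) / 2.0
            else:
                running = running + (P[j] - running) / (step + 1)
        out[i] = running
    return out


def distance_change_to_site(wt_dmap: DistanceMap, mut_dmap: DistanceMap,
                            site: int) -> np.ma.MaskedArray:
    """Relative change of each residue's distance to the mutated site.

    Applies the change rate to the columns ``wt[:, site]`` and
    ``mut[:, site]``; ``site`` is 1-based and its own entry (0/0) is
    masked.  Internal distances are invariant under rigid motion, so no
    superposition of the two structures is needed.
    """
    if len(wt_dmap) != len(mut_dmap):
        raise ValidationError("wild-type and mutant maps differ in size")
    if not 1 <= site <= len(wt_dmap):
        raise IndexError(f"site {site} out of range 1..{len(wt_dmap)}")
    rate = change_rate(wt_dmap.matrix[:, site - 1],
                       mut_dmap.matrix[:, site - 1])
    rate.mask = np.asarray(rate.mask).copy() if rate.mask is not np.ma.nomask \
        else np.zeros(len(rate), dtype=bool)
    rate.mask[site - 1] = True
    return rate


def clip_window(matrix: np.ndarray, site: int, width: int = 31) -> np.ndarray:
    """Clip rows to a window of ``width`` residues centred on ``site``.

    Rows site−(width−1)/2 … site+(width−1)/2 (1-based), zero-padded outside
    the chain, so the centre row (position 16 of 31) is always the mutated
    site — matching the sliding-window geometry of the classifier.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("width must be odd and positive")
    m = np.ma.asarray(matrix, dtype=float)
    was_vector = m.ndim == 1
    if was_vector:
        m = m.reshape(-1, 1)
    L, d = m.shape
    if not 1 <= site <= L:
        raise IndexError(f"site {site} out of range 1..{L}")
    half = width // 2
    out = np.ma.MaskedArray(np.zeros((width, d)),
                            mask=np.zeros((width, d), dtype=bool))
    lo = site - 1 - half
    for w in range(width):
        src = lo + w
        if 0 <= src < L:
            out[w] = m[src]
    if was_vector:
        out = out[:, 0]
    if not isinstance(matrix, np.ma.MaskedArray):
        out = np.asarray(out.filled(0.0))
    return out


@dataclass
class MutationDelta:
    """Aligned wild-type/mutant pair with its three change-rate matrices."""

    site: int                       # 1-based mutated position
    wt_profile: ConservationProfile
    mut_profile: ConservationProfile
    wt_dmap: DistanceMap
    mut_dmap: DistanceMap
    radius: float
    filter_mode: str
    rate_classical: np.ma.MaskedArray   # L×30
    rate_spatial: np.ma.MaskedArray     # L×30
    rate_distance: np.ma.MaskedArray    # L

    def summary(self) -> dict:
        """Residues (1-based) with the largest change-rate magnitudes."""
        spatial_mag = np.ma.abs(self.rate_spatial).max(axis=1)
        dist_mag = np.ma.abs(self.rate_distance)
        return {
            "site": self.site,
            "radius": self.radius,
            "filter_mode": self.filter_mode,
            "max_spatial_rate_residue": int(np.ma.argmax(spatial_mag)) + 1,
            "max_spatial_rate": float(spatial_mag.max()),
            "max_distance_rate_residue": int(np.ma.argmax(dist_mag)) + 1,
            "max_distance_rate": float(dist_mag.max()),
            "n_masked_classical": int(np.ma.getmaskarray(
                self.rate_classical).sum()),
        }

    def to_tsv(self, directory: str | Path, width: int = 31) -> dict[str, Path]:
        """Write the three rate matrices, clipped to the site window."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, mat in (("classical", self.rate_classical),
                          ("spatial", self.rate_spatial),
                          ("distance", self.rate_distance)):
            win = clip_window(mat, self.site, width)
            win2d = np.ma.atleast_2d(win)
            if win2d.shape[0] == 1:
                win2d = win2d.T
            df = pd.DataFrame(np.ma.filled(win2d, np.nan))
            df.insert(0, "window_pos", np.arange(1, width + 1))
            path = directory / f"rate_{name}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            paths[name] = path
        return paths


def compute_mutation_delta(wt_structure: ProteinStructure,
                           mut_structure: ProteinStructure,
                           wt_profile: ConservationProfile,
                           mut_profile: ConservationProfile,
                           site: int, radius: float = 7.0,
                           filter_mode: str = "pairwise") -> MutationDelta:
    """Full change-rate analysis of one point substitution.

    Requires equal wild-type/mutant lengths (a substitution, not an indel).
    ``filter_mode`` selects the sequential-averaging variant ("pairwise",
    the amplified case-study filter) or the plain neighborhood mean
    ("cumulative").
    """
    if len(wt_structure) != len(mut_structure):
        raise ValidationError("wild-type and mutant structures differ in length")
    if len(wt_profile) != len(wt_structure) or \
            len(mut_profile) != len(mut_structure):
        raise ValidationError("profile rows must match structure length")
    if not 1 <= site <= len(wt_structure):
        raise IndexError(f"site {site} out of range 1..{len(wt_structure)}")

    wt_dmap = distance_map(wt_structure)
    mut_dmap = distance_map(mut_structure)
    wt_sp = sequential_spatial_filter(wt_profile, wt_dmap, radius, filter_mode)
    mut_sp = sequential_spatial_filter(mut_profile, mut_dmap, radius,
                                       filter_mode)
    return MutationDelta(
        site=site,
        wt_profile=wt_profile, mut_profile=mut_profile,
        wt_dmap=wt_dmap, mut_dmap=mut_dmap,
        radius=radius, filter_mode=filter_mode,
        rate_classical=change_rate(wt_profile.matrix, mut_profile.matrix),
        rate_spatial=change_rate(wt_sp, mut_sp),
        rate_distance=distance_change_to_site(wt_dmap, mut_dmap, site),
    )
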