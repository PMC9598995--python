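"""Synthetic structures, profiles, DSSP output and labels for testing.

Everything here is synthetic plumbing: the generated files satisfy the
formats and invariants the pipeline relies on (valid PDB/HHM/DSSP, realistic
Cα spacing, ASA bounded by 1.2×MaxASA, exact label rules) but make no
attempt to imitate real AlphaFold confidence or HHblits statistics.

Geometry: ``ideal_helix`` places Cα atoms on an α-helical wheel (radius
2.3 Å, rise 1.5 Å, 100° per residue), giving the realistic ≈3.8 Å
consecutive Cα spacing so that filter-radius sweeps over {0,3,...,11} Å
produce meaningfully different neighborhood sizes; ``perturbed_chain``
adds seeded Gaussian jitter to the helix.  Same seed ⇒ byte-identical
fixtures.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .constants import AMINO_ACIDS, MAX_ASA_THEORETICAL, PROFILE_WIDTH
from .features import distance_map, rasa, spatial_filter
from .structio import (
    ConservationProfile,
    DsspRecord,
    ProteinStructure,
    Residue,
    write_dssp,
    write_hhm,
    write_manifest,
    write_pdb,
)
from .dataset import write_labels

__all__ = [
    "synth_structure",
    "synth_profile",
    "synth_dssp",
    "synth_labels",
    "synth_smoke_proteins",
    "write_fixture_dir",
]

HELIX_RADIUS = 2.3      # Å
HELIX_RISE = 1.5        # Å per residue
HELIX_TWIST = 100.0     # degrees per residue

_SS_CHOICES = "HGIBETS P"   # 8 states + blank, drawn uniformly


def synth_structure(length: int, geometry: str = "ideal_helix",
                    seed: int = 0, sigma: float = 0.3,
                    protein_id: str = "synth") -> ProteinStructure:
    """Generate a synthetic Cα chain with a random sequence.

    ``ideal_helix`` gives consecutive Cα–Cα distances of ≈3.8 Å;
    ``perturbed_chain`` jitters each coordinate by N(0, sigma²).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if geometry not in ("ideal_helix", "perturbed_chain"):
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    ang = np.deg2rad(HELIX_TWIST * t)
    xyz = np.column_stack([
        HELIX_RADIUS * np.cos(ang),
        HELIX_RADIUS * np.sin(ang),
        HELIX_RISE * t,
    ])
    seq = rng.choice(list(AMINO_ACIDS), size=length)
    plddt = rng.uniform(50.0, 99.0, size=length)
    if geometry == "perturbed_chain":
        xyz = xyz + rng.normal(0.0, sigma, size=xyz.shape)
    residues = [
        Residue(seq_index=i + 1, aa=str(seq[i]),
                ca_xyz=tuple(round(float(c), 3) for c in xyz[i]),
                plddt=round(float(plddt[i]), 2))
        for i in range(length)
    ]
    return ProteinStructure(protein_id, residues)


def synth_profile(length: int, seed: int = 0, star_frac: float = 0.02,
                  protein_id: str = "synth"
                  ) -> tuple[ConservationProfile, np.ndarray]:
    """Random conservation profile plus its integer-coded HHM form.

    Raw scores are uniform integers in [0, 6000] (decoded values in
    (0.0156, 1]); a ``star_frac`` fraction of cells carries the ``*``
    sentinel (coded −1 in the raw matrix, decoded to exactly 0).
    """
    rng = np.random.default_rng(seed)
    raw = rng.integers(0, 6001, size=(length, PROFILE_WIDTH))
    stars = rng.random((length, PROFILE_WIDTH)) < star_frac
    raw = np.where(stars, -1, raw)
    decoded = np.where(raw < 0, 0.0, np.power(2.0, -raw / 1000.0))
    return ConservationProfile(protein_id, decoded), raw


def synth_dssp(structure: ProteinStructure, seed: int = 0
               ) -> list[DsspRecord]:
    """Random DSSP records for a structure.

    SS codes are drawn uniformly from the 8 states plus blank; ASA values
    are uniform on [0, 1.2×MaxASA] per residue type, so rASA clipping is
    exercised occasionally.
    """
    rng = np.random.default_rng(seed)
    records = []
    for res in structure.residues:
        ss = str(rng.choice(list(_SS_CHOICES)))
        asa = float(rng.uniform(0.0, 1.2 * MAX_ASA_THEORETICAL[res.aa]))
        records.append(DsspRecord(seq_index=res.seq_index, ss_code=ss,
                                  asa=round(asa)))
    return records


def synth_labels(rule: str, *, length: int | None = None, seed: int = 0,
                 prevalence: float = 0.068, threshold: float = 0.25,
                 structure: ProteinStructure | None = None,
                 dssp_records: list[DsspRecord] | None = None,
                 values: np.ndarray | None = None) -> str:
    """Generate a 0/1 label string under an exactly verifiable rule.

    * ``random_prevalence`` — i.i.d. Bernoulli(prevalence) over ``length``
      residues (default 6.8%, the class balance of the reference
      protein-binding training split);
    * ``rasa_threshold`` — residue is positive iff its rASA (from
      ``structure`` + ``dssp_records``) exceeds ``threshold``;
    * ``profile_threshold`` — positive iff ``values[i] > threshold``.
    """
    if rule == "random_prevalence":
        if length is None:
            raise ValueError("length required for random_prevalence")
        rng = np.random.default_rng(seed)
        bits = rng.random(length) < prevalence
        return "".join("1" if b else "0" for b in bits)
    if rule == "rasa_threshold":
        if structure is None or dssp_records is None:
            raise ValueError("structure and dssp_records required")
        vals = [rasa(rec.asa, res.aa)
                for res, rec in zip(structure.residues, dssp_records)]
        return "".join("1" if v > threshold else "0" for v in vals)
    if rule == "profile_threshold":
        if values is None:
            raise ValueError("values required for profile_threshold")
        return "".join("1" if v > threshold else "0" for v in values)
    raise ValueError(f"unknown label rule {rule!r}")


def synth_smoke_proteins(n_proteins: int = 20, length: int = 60,
                         seed: int = 0, signal_radius: float = 7.0,
                         noise_sigma: float = 0.8, quantile: float = 0.70
                         ) -> list[tuple[ProteinStructure,
                                         ConservationProfile, str]]:
    """Proteins whose labels follow a spatially autocorrelated signal.

    Per protein: a latent per-residue field is built by spatially smoothing
    white noise over ``signal_radius`` Å neighborhoods of a jittered-helix
    chain; labels mark residues above the per-protein ``quantile`` of the
    latent field; profile column 1 observes the field plus strong i.i.d.
    noise and the remaining 29 columns are pure noise.  Spatial filtering
    of the observed profile can denoise the signal, so a radius sweep on
    this data should beat its own 0 Å baseline — the qualitative shape the
    harness asserts.
    """
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_proteins):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        structure = synth_structure(length, "perturbed_chain", seed=sub,
                                    sigma=0.5, protein_id=f"smoke{p:03d}")
        dmap = distance_map(structure)
        prng = np.random.default_rng(sub + 1)
        white = prng.normal(0.0, 1.0, size=(length, 1))
        latent = spatial_filter(white, dmap, signal_radius)[:, 0]
        observed = latent + prng.normal(0.0, noise_sigma, size=length)
        matrix = prng.normal(0.0, noise_sigma, size=(length, PROFILE_WIDTH))
        matrix[:, 0] = observed
        profile = ConservationProfile(structure.protein_id, matrix)
        cut = float(np.quantile(latent, quantile))
        labels = synth_labels("profile_threshold", values=latent,
                              threshold=cut)
        out.append((structure, profile, labels))
    return out


def write_fixture_dir(directory: str | Path, n_proteins: int = 5,
                      length_range: tuple[int, int] = (20, 60),
                      geometry: str = "ideal_helix", seed: int = 0,
                      label_rule: str = "random_prevalence",
                      prevalence: float = 0.068) -> dict:
    """Write a self-contained fixture directory (PDB, HHM, DSSP, labels).

    Returns the manifest dict, which is also written as ``manifest.json``.
    Same seed ⇒ byte-identical directory contents.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = {}
    proteins = []
    for p in range(n_proteins):
        pid = f"fix{p:03d}"
        sub = int(rng.integers(0, 2 ** 31 - 1))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        structure = synth_structure(length, geometry, seed=sub, protein_id=pid)
        profile, raw = synth_profile(length, seed=sub + 1, protein_id=pid)
        records = synth_dssp(structure, seed=sub + 2)
        if label_rule == "rasa_threshold":
            labels = synth_labels("rasa_threshold", structure=structure,
                                  dssp_records=records)
        else:
            labels = synth_labels("random_prevalence", length=length,
                                  seed=sub + 3, prevalence=prevalence)
        write_pdb(structure, directory / f"{pid}.pdb")
        write_hhm(raw, structure.sequence, directory / f"{pid}.hhm",
                  protein_id=pid)
        write_dssp(structure, records, directory / f"{pid}.dssp")
        entries[pid] = (structure.sequence, labels)
        proteins.append({"id": pid, "length": length, "seed": sub})
    write_labels(entries, directory / "labels.txt")
    manifest = {
        "n_proteins": n_proteins,
        "geometry": geometry,
        "label_rule": label_rule,
        "seed": seed,
        "proteins": proteins,
    }
    write_manifest(directory / "manifest.json", **manifest)
    return manifest
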