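"""Readers and writers for the three external per-protein file formats.

Three inputs describe one protein chain:

* a PDB file with the predicted structure (only the Cα atom of each residue
  is kept; the B-factor column of AlphaFold models carries pLDDT),
* an hh-suite ``.hhm`` profile (30 integer-coded columns per residue:
  20 match emissions + 10 transition/diversity values),
* classic ``dssp`` output (8-state secondary structure letter and absolute
  accessible surface area per residue).

Residue indices at this boundary are 1-based throughout; in-memory arrays
are 0-based.  PDB parsing and writing are delegated to :mod:`biotite`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bst_pdb
from biotite.sequence import ProteinSequence

from .constants import AMINO_ACIDS, DSSP_STATES, PROFILE_WIDTH

__all__ = [
    "ParseError",
    "ValidationError",
    "Residue",
    "ProteinStructure",
    "ConservationProfile",
    "DsspRecord",
    "read_pdb",
    "write_pdb",
    "read_hhm",
    "write_hhm",
    "hhm_decode",
    "read_dssp",
    "write_dssp",
    "validate_paired",
    "write_manifest",
]


class ParseError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant (e.g. length mismatch)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue: 1-based sequence index, one-letter code, Cα position."""

    seq_index: int
    aa: str
    ca_xyz: tuple[float, float, float]
    plddt: float | None = None


@dataclass
class ProteinStructure:
    """An ordered single-chain protein backbone reduced to Cα positions."""

    protein_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"{self.protein_id}: empty structure")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"{self.protein_id}: residue indices not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """L×3 float array of Cα coordinates in Å (row i = i-th residue)."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)


@dataclass
class ConservationProfile:
    """L×30 per-residue conservation matrix derived from an HHblits search."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != PROFILE_WIDTH:
            raise ValidationError(
                f"{self.protein_id}: profile must be L×{PROFILE_WIDTH}, "
                f"got {self.matrix.shape}"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DsspRecord:
    """One row of classic DSSP output: index, SS letter (or blank), ASA."""

    seq_index: int
    ss_code: str
    asa: float

    def __post_init__(self) -> None:
        if self.ss_code not in DSSP_STATES:
            raise ValidationError(
                f"residue {self.seq_index}: invalid SS code {self.ss_code!r}"
            )
        if self.asa < 0:
            raise ValidationError(f"residue {self.seq_index}: ASA < 0")


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def read_pdb(path: str | Path, chain_id: str | None = None,
             protein_id: str | None = None) -> ProteinStructure:
    """Read a single-chain PDB file into a :class:`ProteinStructure`.

    One entry per residue is taken from its ``CA`` ATOM record; the B-factor
    column is stored as pLDDT metadata.  Insertion codes and alternate
    locations are rejected (AlphaFold models contain neither), as are files
    with several chains unless ``chain_id`` selects one.
    """
    path = Path(path)
    pdb_file = bst_pdb.PDBFile.read(path)
    atoms = pdb_file.get_structure(model=1, altloc="all",
                                   extra_fields=["b_factor"])
    atoms = atoms[bst.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ParseError(f"{path}: no amino-acid ATOM records")

    if np.any(atoms.ins_code != ""):
        raise ParseError(f"{path}: insertion codes are not supported")
    altloc = atoms.get_annotation("altloc_id")
    if np.any(~np.isin(altloc, ("", " ", "."))):
        raise ParseError(f"{path}: alternate locations are not supported")

    chains = np.unique(atoms.chain_id)
    if chain_id is None:
        if len(chains) > 1:
            raise ParseError(
                f"{path}: multiple chains {list(chains)}; pass chain_id"
            )
    else:
        if chain_id not in chains:
            raise ParseError(f"{path}: no chain {chain_id!r}")
        atoms = atoms[atoms.chain_id == chain_id]

    is_ca = atoms.atom_name == "CA"
    all_res_ids = np.unique(atoms.res_id)
    ca = atoms[is_ca]
    missing = np.setdiff1d(all_res_ids, ca.res_id)
    if missing.size:
        raise ParseError(
            f"{path}: residue {int(missing[0])} has no CA atom"
        )
    dup = np.unique(ca.res_id, return_counts=True)
    if np.any(dup[1] > 1):
        bad = int(dup[0][dup[1] > 1][0])
        raise ParseError(f"{path}: residue {bad} has multiple CA atoms")

    order = np.argsort(ca.res_id, kind="stable")
    ca = ca[order]
    residues = []
    for i in range(ca.array_length()):
        try:
            one = ProteinSequence.convert_letter_3to1(ca.res_name[i])
        except Exception as exc:  # non-standard residue name
            raise ParseError(
                f"{path}: unknown residue name {ca.res_name[i]!r} "
                f"at {int(ca.res_id[i])}"
            ) from exc
        residues.append(Residue(
            seq_index=int(ca.res_id[i]),
            aa=one,
            ca_xyz=tuple(float(x) for x in ca.coord[i]),
            plddt=float(ca.b_factor[i]),
        ))
    return ProteinStructure(protein_id or path.stem, residues)


def write_pdb(structure: ProteinStructure, path: str | Path,
              chain_id: str = "A") -> None:
    """Write the Cα trace of ``structure`` as PDB ATOM records."""
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.ca_coords
    arr.chain_id = np.full(n, chain_id)
    arr.res_id = np.array([r.seq_index for r in structure.residues])
    arr.res_name = np.array([
        ProteinSequence.convert_letter_1to3(r.aa) for r in structure.residues
    ])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    arr.set_annotation("b_factor", np.array(
        [r.plddt if r.plddt is not None else 0.0 for r in structure.residues]
    ))
    out = bst_pdb.PDBFile()
    out.set_structure(arr)
    out.write(str(path))


# --------------------------------------------------------------------------
# hh-suite HHM profiles
# --------------------------------------------------------------------------

def hhm_decode(token: str) -> float:
    """Decode one integer-coded HHM score to a probability-scale value.

    hh-suite stores ``-1000*log2(p)`` rounded to integer, so the inverse is
    ``2**(-x/1000)``; the ``*`` sentinel (probability zero) maps to 0.0.
    """
    if token == "*":
        return 0.0
    return math.pow(2.0, -int(token) / 1000.0)


def read_hhm(path: str | Path, protein_id: str | None = None,
             raw: bool = False) -> ConservationProfile:
    """Parse an hh-suite ``.hhm`` file into an L×30 conservation profile.

    Columns 1–20 are the match-emission scores (order ``ACDEFGHIKLMNPQRSTVWY``),
    columns 21–30 the seven transition scores plus the three Neff columns.
    With ``raw=True`` the integer codes are returned unconverted (``*`` → nan),
    otherwise every column is decoded with :func:`hhm_decode`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    hmm_at = next(
        (i for i, l in enumerate(lines) if l.startswith("HMM")), None
    )
    if hmm_at is None:
        raise ParseError(f"{path}: no 'HMM' header line (malformed HHM file)")

    def decode(tok: str, lineno: int) -> float:
        if raw:
            return math.nan if tok == "*" else float(int(tok))
        try:
            return hhm_decode(tok)
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: bad score token {tok!r}"
            ) from exc

    rows: list[list[float]] = []
    i = hmm_at + 1
    while i < len(lines):
        line = lines[i]
        if line.startswith("//"):
            break
        tok = line.split()
        # a residue block starts "X <idx> <20 scores> <align col>"
        if len(tok) >= 2 and len(tok[0]) == 1 and tok[0] in AMINO_ACIDS + "X" \
                and tok[1].isdigit():
            if len(tok) < 22:
                raise ParseError(
                    f"{path}:{i + 1}: truncated match-emission line "
                    f"({len(tok) - 2} of 20 scores)"
                )
            emis = [decode(t, i + 1) for t in tok[2:22]]
            i += 1
            while i < len(lines) and not lines[i].split():
                i += 1
            if i >= len(lines) or lines[i].startswith("//"):
                raise ParseError(
                    f"{path}:{i}: residue block truncated before "
                    "transition line"
                )
            ttok = lines[i].split()
            if len(ttok) < 10:
                raise ParseError(
                    f"{path}:{i + 1}: transition line has {len(ttok)} of "
                    "10 fields"
                )
            trans = [decode(t, i + 1) for t in ttok[:10]]
            rows.append(emis + trans)
        i += 1

    if not rows:
        raise ParseError(f"{path}: no residue blocks after HMM header")
    matrix = np.array(rows, dtype=float)
    return ConservationProfile(protein_id or path.stem, matrix)


def write_hhm(raw_scores: np.ndarray, sequence: str, path: str | Path,
              protein_id: str = "synthetic") -> None:
    """Write integer-coded scores as a minimal, conformant ``.hhm`` file.

    ``raw_scores`` is L×30 of integers; negative entries encode the ``*``
    (zero-probability) sentinel.  Only the fields needed by :func:`read_hhm`
    and real hh-suite consumers are emitted.
    """
    raw_scores = np.asarray(raw_scores)
    L = raw_scores.shape[0]
    if raw_scores.shape != (L, PROFILE_WIDTH) or L != len(sequence):
        raise ValidationError("raw_scores must be L×30 matching sequence")

    def fmt(v: int | float) -> str:
        return "*" if v < 0 else str(int(v))

    out = [
        "HHsearch 1.5",
        f"NAME  {protein_id}",
        f"LENG  {L} match states, {L} columns in multiple alignment",
        "NEFF  1.0",
        "SEQ",
        f">{protein_id}",
        sequence,
        "#",
        "NULL   " + "\t".join(["3706"] * 20),
        "HMM    " + "\t".join(AMINO_ACIDS),
        "       " + "\t".join(
            ("M->M", "M->I", "M->D", "I->M", "I->I", "D->M", "D->D",
             "Neff", "Neff_I", "Neff_D")
        ),
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, aa in enumerate(sequence):
        emis = "\t".join(fmt(v) for v in raw_scores[i, :20])
        trans = "\t".join(fmt(v) for v in raw_scores[i, 20:])
        out.append(f"{aa} {i + 1}\t{emis}\t{i + 1}")
        out.append(f"       {trans}")
        out.append("")
    out.append("//")
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# classic DSSP output
# --------------------------------------------------------------------------

_DSSP_HEADER_TAG = "#  RESIDUE"


def read_dssp(path: str | Path) -> list[DsspRecord]:
    """Parse classic DSSP output into per-residue records, in file order.

    Chain-break rows (``!`` in the AA column) are skipped; a single
    :class:`UserWarning` reports how many were seen.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = next(
        (i for i, l in enumerate(lines) if l.lstrip().startswith(_DSSP_HEADER_TAG)),
        None,
    )
    if start is None:
        raise ParseError(f"{path}: missing '  #  RESIDUE' header line")

    records: list[DsspRecord] = []
    n_breaks = 0
    for lineno, line in enumerate(lines[start + 1:], start + 2):
        if len(line) < 38:
            if line.strip():
                raise ParseError(f"{path}:{lineno}: short data row")
            continue
        if line[13] == "!":
            n_breaks += 1
            continue
        try:
            seq_index = int(line[5:10])
            ss = line[16]
            asa = float(int(line[34:38]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed data row") from exc
        records.append(DsspRecord(seq_index=seq_index, ss_code=ss, asa=asa))
    if n_breaks:
        warnings.warn(
            f"{path}: skipped {n_breaks} chain-break row(s)", stacklevel=2
        )
    if not records:
        raise ParseError(f"{path}: no residue rows")
    return records


def write_dssp(structure: ProteinStructure, records: list[DsspRecord],
               path: str | Path, chain_id: str = "A") -> None:
    """Write records in the classic fixed-column DSSP layout.

    Emits the full-width rows (h-bond, angle and Cα-coordinate fields are
    zero-filled) so that strict third-party parsers accept the file.
    """
    if len(structure) != len(records):
        raise ValidationError("structure and DSSP records differ in length")
    hdr = (
        "==== Secondary Structure Definition by the program DSSP "
        "==== SYNTHETIC ====\n"
        f"  {len(records):4d}  1  0  0  0   TOTAL NUMBER OF RESIDUES, NUMBER "
        "OF CHAINS, NUMBER OF SS-BRIDGES\n"
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   "
        "Z-CA\n"
    )

    def place(buf: list[str], start: int, text: str) -> None:
        buf[start:start + len(text)] = list(text)

    rows = []
    for n, (res, rec) in enumerate(zip(structure.residues, records), 1):
        buf = [" "] * 136
        place(buf, 0, f"{n:5d}")
        place(buf, 5, f"{rec.seq_index:5d}")
        buf[11] = chain_id
        buf[13] = res.aa
        buf[16] = rec.ss_code
        place(buf, 25, f"{0:4d}{0:4d}")          # BP1 BP2
        place(buf, 34, f"{int(round(rec.asa)):4d}")
        # four h-bond (relidx, energy) pairs, zeroed
        place(buf, 38, f"{0:7d},{0.0:4.1f}")
        place(buf, 50, f"{0:6d},{0.0:4.1f}")
        place(buf, 61, f"{0:6d},{0.0:4.1f}")
        place(buf, 72, f"{0:6d},{0.0:4.1f}")
        place(buf, 85, f"{0.0:6.3f}")            # TCO
        place(buf, 91, f"{360.0:6.1f}{360.0:6.1f}")  # KAPPA ALPHA
        place(buf, 103, f"{360.0:6.1f}{360.0:6.1f}")  # PHI PSI
        x, y, z = res.ca_xyz
        place(buf, 115, f"{x:7.1f}{y:7.1f}{z:7.1f}")
        rows.append("".join(buf).rstrip())
    Path(path).write_text(hdr + "\n".join(rows) + "\n")


# --------------------------------------------------------------------------
# paired validation & manifests
# --------------------------------------------------------------------------

def validate_paired(structure: ProteinStructure,
                    profile: ConservationProfile | None = None,
                    dssp_records: list[DsspRecord] | None = None) -> None:
    """Assert that per-protein inputs agree in length; never truncate."""
    L = len(structure)
    if profile is not None and len(profile) != L:
        raise ValidationError(
            f"{structure.protein_id}: structure has {L} residues but "
            f"profile has {len(profile)} rows"
        )
    if dssp_records is not None and len(dssp_records) != L:
        raise ValidationError(
            f"{structure.protein_id}: structure has {L} residues but "
            f"DSSP has {len(dssp_records)} rows"
        )


def write_manifest(path: str | Path, **entries) -> None:
    """Write a small JSON run manifest (parameters, provenance, seeds)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
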