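"""Shared alphabets and reference tables.

All residue indices exposed at module boundaries are 1-based (PDB/DSSP
convention); numpy array rows are 0-based internally.
"""

# Canonical 20-letter alphabet in the column order used by hh-suite HHM
# emission columns (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# hh-suite HHM transition/diversity columns following the 20 emissions.
HHM_TRANSITION_COLUMNS = (
    "M->M", "M->I", "M->D", "I->M", "I->I", "D->M", "D->D",
    "Neff", "Neff_I", "Neff_D",
)

#: Number of columns in an HHblits profile (20 emissions + 10 transitions).
PROFILE_WIDTH = 30

# Eight-state DSSP secondary-structure alphabet; blank means "no structure"
# and newer mkdssp versions additionally emit 'P' (polyproline II).
DSSP_STATES = frozenset("HGIBETSP ")

# Maximum accessible surface area per residue type, in Å^2.
# Theoretical upper bounds of Tien et al. (2013), the standard normalisation
# table for relative ASA.  Override-able wherever rASA is computed.
MAX_ASA_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
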