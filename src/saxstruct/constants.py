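"""Physical constants and residue-level lookup tables.

Electron counts are for the neutral residue (amino acid minus one water),
used as coarse-grained form factors in residue-level Debye sums. Average
masses follow the standard ExPASy/IUPAC average atomic weights.
"""

from __future__ import annotations

# electrons per residue (amino acid minus H2O), neutral protonation
RESIDUE_ELECTRONS: dict[str, int] = {
    "GLY": 30, "ALA": 38, "SER": 46, "PRO": 52, "VAL": 54,
    "THR": 54, "CYS": 54, "LEU": 62, "ILE": 62, "ASN": 60,
    "ASP": 60, "GLN": 68, "LYS": 70, "GLU": 68, "MET": 70,
    "HIS": 72, "PHE": 78, "ARG": 84, "TYR": 86, "TRP": 98,
}

# average residue masses in Da (amino acid minus H2O)
RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

ONE_TO_THREE: dict[str, str] = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL",
    "T": "THR", "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN",
    "D": "ASP", "Q": "GLN", "K": "LYS", "E": "GLU", "M": "MET",
    "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
}

WATER_MASS = 18.01524  # Da

# Porod volume -> molecular weight divisor, A^3 per Da (protein-typical)
POROD_VOLUME_PER_DALTON = 1.6

# mean electrons per residue, used when a residue name is unknown
MEAN_RESIDUE_ELECTRONS = 62.0

CA_CA_DISTANCE = 3.8  # A, trans peptide virtual bond
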