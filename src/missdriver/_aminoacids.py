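"""Amino-acid constants shared across the feature stack.

All per-residue tables are keyed by one-letter code over the canonical
20-letter alphabet; ``X`` marks unknown/non-standard residues and is
excluded from feature extraction.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA20)
AA_WITH_X = frozenset(AA20 + "X")

# PSI-BLAST ascii PSSM column order.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

# Non-standard letters folded to X on ingest (selenocysteine, ambiguity codes).
FOLD_TO_X = {"U": "X", "B": "X", "Z": "X", "J": "X", "O": "X"}

# Six physicochemical side-chain classes covering all 20 residues.
SIX_CLASSES = {
    "aliphatic": frozenset("GAVLIP"),
    "sulfur": frozenset("CM"),
    "aromatic": frozenset("FWY"),
    "polar": frozenset("STNQ"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
}
SIX_CLASS_ORDER = ("aliphatic", "sulfur", "aromatic", "polar", "positive", "negative")

# Theoretical maximum accessible surface area per residue (Tien et al. 2013), A^2.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Van der Waals radii by element, A. Unlisted elements fall back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70


def vdw_radius(atom_name: str) -> float:
    """Radius for a PDB atom name; the element is its first alphabetic character."""
    for ch in atom_name:
        if ch.isalpha():
            return VDW_RADII.get(ch.upper(), DEFAULT_VDW)
    return DEFAULT_VDW
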