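"""Amino-acid lookup tables shared across modules."""

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to the parent amino acid
    "MSE": "M", "SEC": "C", "PYL": "K", "CSO": "C", "CME": "C",
    "OCS": "C", "SEP": "S", "TPO": "T", "PTR": "Y", "MLY": "K",
    "M3L": "K", "HYP": "P", "KCX": "K", "CSD": "C", "FME": "M",
    "LLP": "K", "PCA": "E",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

# residue grouping used for the composition features
POLAR_AA = frozenset("GNPQST")
HYDROPHOBIC_AA = frozenset("ACILMV")

# Theoretical maximum accessible surface areas (A^2) per residue,
# Tien et al. 2013, used as the denominator of relative ASA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# van der Waals radii (A) per element for SASA; unknown heavy atoms
# fall back to 1.80 A.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "D": 1.20,
}
DEFAULT_VDW = 1.80
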