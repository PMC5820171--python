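"""Static amino-acid chemistry tables shared by featurization and site centers."""

from __future__ import annotations

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

POSITIVE_RESIDUES = {"ARG", "LYS", "HIS"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}

RESIDUE_CLASSES = {
    "hydrophobic": {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"},
    "polar": {"SER", "THR", "TYR", "ASN", "GLN", "CYS"},
    "acidic": {"ASP", "GLU"},
    "basic": {"LYS", "ARG", "HIS"},
    "amide": {"ASN", "GLN"},
    "sulfur": {"CYS", "MET"},
    "small": {"GLY", "ALA", "SER", "CYS", "THR"},
    "aromatic": {"PHE", "TYR", "TRP", "HIS"},
}

AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

# hydrogen-bond capable heavy atoms (donor carries the H, acceptor the lone pair)
HBOND_DONORS = {
    ("*", "N"),  # backbone amide
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("SER", "OG"), ("THR", "OG1"), ("TRP", "NE1"),
    ("TYR", "OH"), ("CYS", "SG"),
}
HBOND_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("MET", "SD"),
}

FUNCTIONAL_GROUP_ATOMS = {
    "hydroxyl": {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")},
    "carboxylate": {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")},
    "amide": {("ASN", "ND2"), ("ASN", "OD1"), ("GLN", "NE2"), ("GLN", "OE1")},
    "guanidinium": {("ARG", "CZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")},
    "imidazole": {("HIS", "CG"), ("HIS", "ND1"), ("HIS", "CD2"), ("HIS", "CE1"), ("HIS", "NE2")},
    "thiol_thioether": {("CYS", "SG"), ("MET", "SD")},
}

# formal charge distributed over the charged group's terminal heavy atoms
FORMAL_CHARGE_ATOMS = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
}
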