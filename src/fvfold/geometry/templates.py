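"""Idealized residue geometry: rigid-group templates and chi definitions.

The all-atom reconstruction step places side-chain atoms by rotating
idealized rigid groups about the chi axes, so the package ships a static
internal-coordinate table.  Each side-chain atom is defined by a Z-matrix
style entry: a bonded parent ``p1``, two reference atoms ``p2``/``p3``, an
ideal bond length (Angstrom), an ideal bond angle p2-p1-atom (degrees), and a
torsion about the p2-p1 axis that is either a fixed value or ``chi_k`` plus a
fixed offset.

Provenance: bond lengths and angles are rounded literature values in the
Engh & Huber tradition of idealized protein stereochemistry, as used across
idealized-reconstruction codes.  They are a repository asset: the tests and
the violation loss treat this table as the definition of "ideal", so internal
consistency, not provenance, is what is verified.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AA3",
    "AA1",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "SIDECHAIN_TEMPLATES",
    "CHI_ATOMS",
    "CHI_COUNT",
    "SYMMETRIC_CHI",
    "BACKBONE_BONDS",
    "BACKBONE_ANGLES",
    "PEPTIDE_BOND_LENGTH",
    "VDW_RADII",
    "atom_element",
]

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA1 = list("ARNDCQEGHILKMFPSTWYV")
ONE_TO_THREE = dict(zip(AA1, AA3))
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# torsion spec: ("chi", k, offset_deg) with k in 1..4, or ("fixed", deg)
# entry: (atom, (p1, p2, p3), bond_A, angle_deg, torsion)
_CB = ("CB", ("CA", "N", "C"), 1.530, 110.5, ("fixed", -122.6))

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("CB", "CA", "N"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", ("CB", "CA", "N"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        _CB,
        ("OG1", ("CB", "CA", "N"), 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        _CB,
        ("CG1", ("CB", "CA", "N"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("CB", "CA", "N"), 1.527, 110.5, ("chi", 1, -122.3)),
    ],
    "LEU": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.521, 110.7, ("chi", 2, 122.5)),
    ],
    "ILE": [
        _CB,
        ("CG1", ("CB", "CA", "N"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi", 1, -122.3)),
        ("CD1", ("CG1", "CB", "CA"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CG", "CB", "CA"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("SD", "CG", "CB"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "PHE": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CD1", "CG", "CB"), 1.382, 120.8, ("fixed", 180.0)),
        ("CE2", ("CD2", "CG", "CB"), 1.382, 120.8, ("fixed", 180.0)),
        ("CZ", ("CE1", "CD1", "CG"), 1.382, 120.0, ("fixed", 0.0)),
    ],
    "TYR": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CD1", "CG", "CB"), 1.382, 121.2, ("fixed", 180.0)),
        ("CE2", ("CD2", "CG", "CB"), 1.382, 121.2, ("fixed", 180.0)),
        ("CZ", ("CE1", "CD1", "CG"), 1.378, 119.6, ("fixed", 0.0)),
        ("OH", ("CZ", "CE1", "CD1"), 1.376, 119.9, ("fixed", 180.0)),
    ],
    "TRP": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", ("CD1", "CG", "CB"), 1.374, 110.2, ("fixed", 180.0)),
        ("CE2", ("CD2", "CG", "CB"), 1.409, 107.3, ("fixed", 180.0)),
        ("CE3", ("CD2", "CG", "CB"), 1.398, 133.9, ("fixed", 0.0)),
        ("CZ2", ("CE2", "CD2", "CG"), 1.394, 122.4, ("fixed", 180.0)),
        ("CZ3", ("CE3", "CD2", "CG"), 1.382, 118.7, ("fixed", 180.0)),
        ("CH2", ("CZ2", "CE2", "CD2"), 1.368, 117.5, ("fixed", 180.0)),
    ],
    "ASP": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CG", "CB", "CA"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CG", "CB", "CA"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CG", "CB", "CA"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CG", "CB", "CA"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CD", "CG", "CB"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", ("CD", "CG", "CB"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CD", "CG", "CB"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CD", "CG", "CB"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CD", "CG", "CB"), 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", ("CE", "CD", "CG"), 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CD", "CG", "CB"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("NE", "CD", "CG"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CZ", "NE", "CD"), 1.326, 120.0, ("fixed", 0.0)),
        ("NH2", ("CZ", "NE", "CD"), 1.326, 120.0, ("fixed", 180.0)),
    ],
    "HIS": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CG", "CB", "CA"), 1.371, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.356, 131.2, ("chi", 2, 180.0)),
        ("CE1", ("ND1", "CG", "CB"), 1.319, 109.0, ("fixed", 180.0)),
        ("NE2", ("CD2", "CG", "CB"), 1.374, 107.2, ("fixed", 180.0)),
    ],
    "PRO": [
        _CB,
        ("CG", ("CB", "CA", "N"), 1.492, 104.5, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.503, 106.1, ("chi", 2, 0.0)),
    ],
}

# chi_k measured as dihedral(a, b, c, d); consistent with the build torsions
# above so reconstruction is a right-inverse of measurement.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "GLN": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ALA": [],
    "GLY": [],
}

CHI_COUNT = {aa: len(v) for aa, v in CHI_ATOMS.items()}

# terminal groups that are indistinguishable under a 180-degree flip of the
# named chi; the alternate torsion target for the angle loss
SYMMETRIC_CHI: dict[str, int] = {"ASP": 2, "GLU": 3, "PHE": 2, "TYR": 2}

# backbone stereochemistry (idealized); O is built off C with torsion
# defined by the local psi of the generator
BACKBONE_BONDS = {("N", "CA"): 1.458, ("CA", "C"): 1.525, ("C", "O"): 1.231}
BACKBONE_ANGLES = {  # degrees
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N+"): 116.2,  # to the next residue's N
    ("C", "N+", "CA+"): 121.7,
    ("O", "C", "N+"): 123.0,
}
PEPTIDE_BOND_LENGTH = 1.329  # C(i) - N(i+1)

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def atom_element(name: str) -> str:
    """Element of a standard protein heavy atom from its PDB name."""
    return name[0]


def sidechain_bond_table(resname: str) -> list[tuple[str, str, float]]:
    """(atom, parent, ideal length) pairs for a residue's side chain."""
    return [(a, p[0], bond) for a, p, bond, _ang, _tor in SIDECHAIN_TEMPLATES[resname]]


def sidechain_angle_table(resname: str) -> list[tuple[str, str, str, float]]:
    """(p2, p1, atom, ideal angle deg) triples for a residue's side chain."""
    return [
        (p[1], p[0], a, ang) for a, p, _bond, ang, _tor in SIDECHAIN_TEMPLATES[resname]
    ]


_IDEAL_N_ANGLE = np.deg2rad(BACKBONE_ANGLES[("N", "CA", "C")])

#: Local (frame) coordinates of the backbone atoms under the frame convention
#: (x along CA->C, N in the xy-plane with positive y).
BACKBONE_LOCAL = {
    "CA": np.zeros(3),
    "C": np.array([BACKBONE_BONDS[("CA", "C")], 0.0, 0.0]),
    "N": BACKBONE_BONDS[("N", "CA")]
    * np.array([np.cos(_IDEAL_N_ANGLE), np.sin(_IDEAL_N_ANGLE), 0.0]),
}
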