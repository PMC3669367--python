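"""Embedded chemical tables: residue topology, ideal internal coordinates,
a compact backbone-independent rotamer library, hydrogen-bond donor/acceptor
roles and formal side-chain charges.

Internal-coordinate templates use ideal bond lengths/angles (Engh-Huber-like
values) and are the single source of geometry for fixture construction and
side-chain rebuilding.  A torsion is either a fixed float (degrees) or a
``("chi", k, offset)`` triple meaning "k-th chi angle plus offset".
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_AA = frozenset(AA1_TO_3)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: formal side-chain charge at neutral pH; histidine deliberately neutral
FORMAL_CHARGE = {"R": 1, "K": 1, "D": -1, "E": -1}

#: representative atom of the charged group, used by the pair term
CHARGED_GROUP_ATOM = {"R": "CZ", "K": "NZ", "D": "CG", "E": "CD"}

Chi = tuple  # ("chi", k, offset)


def _chi(k: int, offset: float = 0.0) -> Chi:
    return ("chi", k, offset)


# (atom, element, (ref1, ref2, ref3), bond, angle, torsion)
# placed atom X satisfies: |ref3-X| = bond, angle(ref2, ref3, X) = angle,
# torsion(ref1, ref2, ref3, X) = torsion.  CB is first for all non-GLY types.
_CB = ("CB", "C", ("N", "C", "CA"), 1.530, 110.6, 122.6)

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "C": [_CB, ("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "T": [_CB,
          ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
          ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "V": [_CB,
          ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, _chi(1)),
          ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, _chi(1, 122.0))],
    "I": [_CB,
          ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
          ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
          ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "L": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.524, 110.7, _chi(2)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.525, 110.4, _chi(2, 122.0))],
    "M": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
          ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "F": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.0, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.0, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "Y": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.0, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.0, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
          ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "W": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.7, _chi(2, 180.0)),
          ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
          ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
          ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
          ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
          ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "D": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.5, _chi(2)),
          ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.5, _chi(2, 180.0))],
    "N": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
          ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "E": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.5, _chi(3)),
          ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.5, _chi(3, 180.0))],
    "Q": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
          ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "K": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
          ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
          ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "R": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
          ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
          ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
          ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
          ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "H": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
          ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.354, 131.2, _chi(2, 180.0)),
          ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
          ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "P": [_CB,
          ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, _chi(1)),
          ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, _chi(2))],
}

#: chi-angle defining atom quadruples, in order chi1, chi2, ...
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "S": [("N", "CA", "CB", "OG")],
    "C": [("N", "CA", "CB", "SG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "A": [], "G": [],
}

#: compact backbone-independent rotamer library: (chi tuple, prior probability)
ROTAMER_LIBRARY: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "A": [((), 1.0)],
    "G": [((), 1.0)],
    "P": [((-25.0, 38.0), 1.0)],
    "S": [((-60.0,), 0.48), ((180.0,), 0.30), ((60.0,), 0.22)],
    "C": [((-60.0,), 0.48), ((180.0,), 0.30), ((60.0,), 0.22)],
    "T": [((-60.0,), 0.48), ((180.0,), 0.30), ((60.0,), 0.22)],
    "V": [((-60.0,), 0.22), ((180.0,), 0.56), ((60.0,), 0.22)],
    "I": [((-60.0, 170.0), 0.55), ((-60.0, -60.0), 0.15),
          ((180.0, 165.0), 0.18), ((60.0, 170.0), 0.12)],
    "L": [((-60.0, 175.0), 0.55), ((180.0, 65.0), 0.28),
          ((-60.0, 65.0), 0.10), ((180.0, 175.0), 0.07)],
    "M": [((-60.0, 180.0, 75.0), 0.28), ((-60.0, 180.0, -75.0), 0.28),
          ((-60.0, -60.0, -70.0), 0.22), ((180.0, 180.0, 75.0), 0.22)],
    "F": [((-60.0, 90.0), 0.50), ((180.0, 80.0), 0.33), ((60.0, 90.0), 0.17)],
    "Y": [((-60.0, 90.0), 0.50), ((180.0, 80.0), 0.33), ((60.0, 90.0), 0.17)],
    "W": [((-60.0, 90.0), 0.50), ((180.0, 80.0), 0.33), ((60.0, 90.0), 0.17)],
    "H": [((-60.0, 90.0), 0.50), ((180.0, 80.0), 0.33), ((60.0, 90.0), 0.17)],
    "D": [((-60.0, -20.0), 0.47), ((180.0, 10.0), 0.34), ((60.0, -20.0), 0.19)],
    "N": [((-60.0, -20.0), 0.47), ((180.0, 10.0), 0.34), ((60.0, -20.0), 0.19)],
    "E": [((-60.0, 180.0, -20.0), 0.38), ((180.0, 180.0, 0.0), 0.30),
          ((-60.0, -60.0, -30.0), 0.20), ((60.0, 180.0, 0.0), 0.12)],
    "Q": [((-60.0, 180.0, -20.0), 0.38), ((180.0, 180.0, 0.0), 0.30),
          ((-60.0, -60.0, -30.0), 0.20), ((60.0, 180.0, 0.0), 0.12)],
    "K": [((-60.0, 180.0, 180.0, 180.0), 0.40), ((180.0, 180.0, 180.0, 180.0), 0.33),
          ((-60.0, -60.0, 180.0, 180.0), 0.15), ((60.0, 180.0, 180.0, 180.0), 0.12)],
    "R": [((-60.0, 180.0, 180.0, 180.0), 0.37), ((180.0, 180.0, 180.0, 180.0), 0.30),
          ((-60.0, 180.0, -90.0, 180.0), 0.18), ((-60.0, -60.0, 180.0, 180.0), 0.15)],
}

#: side-chain H-bond donor heavy atoms as (donor_atom, base_atom)
SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "R": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "K": [("NZ", "CE")],
    "N": [("ND2", "CG")],
    "Q": [("NE2", "CD")],
    "H": [("ND1", "CG"), ("NE2", "CE1")],
    "W": [("NE1", "CD1")],
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "Y": [("OH", "CZ")],
}

#: side-chain H-bond acceptor heavy atoms as (acceptor_atom, base_atom)
SIDECHAIN_ACCEPTORS: dict[str, list[tuple[str, str]]] = {
    "D": [("OD1", "CG"), ("OD2", "CG")],
    "E": [("OE1", "CD"), ("OE2", "CD")],
    "N": [("OD1", "CG")],
    "Q": [("OE1", "CD")],
    "H": [("ND1", "CG"), ("NE2", "CE1")],
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "Y": [("OH", "CZ")],
}

#: backbone donor/acceptor (all residue types; proline N cannot donate)
BACKBONE_DONOR = ("N", "CA")
BACKBONE_ACCEPTORS = (("O", "C"), ("OXT", "C"))

#: per-element Lennard-Jones parameters: van-der-Waals radius (A), well depth
LJ_PARAMS = {
    "C": (1.80, 0.10),
    "N": (1.65, 0.17),
    "O": (1.55, 0.21),
    "S": (2.00, 0.25),
}
LJ_DEFAULT = (1.80, 0.10)


def atom_element(name: str) -> str:
    """Element symbol from a PDB heavy-atom name (first alphabetic character)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def sidechain_atom_names(aa: str) -> list[str]:
    return [entry[0] for entry in SIDECHAIN_TEMPLATES[aa]]
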