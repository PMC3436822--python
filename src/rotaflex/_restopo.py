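"""Ideal-geometry residue topology.

Side chains are described as z-matrix rows (atom, three reference atoms, bond
length, bond angle, dihedral).  The dihedral is either a fixed value or a chi
torsion (optionally with a constant offset) so a residue can be constructed
at any target chi vector.  Bond lengths/angles are standard Engh & Huber-type
ideal values; they only need to be good enough for exact chi round-trips and
realistic sterics, not for refinement.
"""
from __future__ import annotations

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# ("name", "element", ref_a, ref_b, ref_c, length, angle, dihedral)
# dihedral: float -> fixed; ("chi", i, offset) -> chi_i + offset degrees.
# place_atom(a, b, c, ...) sets the new atom D with torsion a-b-c-D.
SIDE_CHAIN_ZMAT: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "O", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "S", "N", "CA", "CB", 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "O", "N", "CA", "CB", 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", "C", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", "C", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 122.0)),
    ],
    "ILE": [
        ("CG1", "C", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "C", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", "C", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "LEU": [
        ("CG", "C", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", "CA", "CB", "CG", 1.524, 110.7, ("chi", 2, 0.0)),
        ("CD2", "C", "CA", "CB", "CG", 1.524, 110.7, ("chi", 2, 122.0)),
    ],
    "MET": [
        ("CG", "C", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", "S", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "PRO": [
        ("CG", "C", "N", "CA", "CB", 1.495, 104.5, ("chi", 1, 0.0)),
        ("CD", "C", "CA", "CB", "CG", 1.507, 105.5, ("chi", 2, 0.0)),
    ],
    "PHE": [
        ("CG", "C", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", "CB", "CG", "CD1", 1.393, 120.5, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", 1.393, 120.5, 180.0),
        ("CZ", "C", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "C", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", "CB", "CG", "CD1", 1.393, 120.5, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", 1.393, 120.5, 180.0),
        ("CZ", "C", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
        ("OH", "O", "CD1", "CE1", "CZ", 1.377, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "C", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "C", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "C", "CA", "CB", "CG", 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", "N", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
        ("CE3", "C", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
        ("CZ2", "C", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
        ("CZ3", "C", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
        ("CH2", "C", "CD2", "CE2", "CZ2", 1.368, 117.5, 180.0),
    ],
    "HIS": [
        ("CG", "C", "N", "CA", "CB", 1.492, 113.7, ("chi", 1, 0.0)),
        ("ND1", "N", "CA", "CB", "CG", 1.380, 122.7, ("chi", 2, 0.0)),
        ("CD2", "C", "CA", "CB", "CG", 1.354, 131.1, ("chi", 2, 180.0)),
        ("CE1", "C", "CB", "CG", "ND1", 1.326, 109.2, 180.0),
        ("NE2", "N", "CB", "CG", "CD2", 1.373, 107.1, 180.0),
    ],
    "ASP": [
        ("CG", "C", "N", "CA", "CB", 1.516, 112.9, ("chi", 1, 0.0)),
        ("OD1", "O", "CA", "CB", "CG", 1.249, 118.5, ("chi", 2, 0.0)),
        ("OD2", "O", "CA", "CB", "CG", 1.249, 118.5, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", "N", "CA", "CB", 1.516, 112.7, ("chi", 1, 0.0)),
        ("OD1", "O", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "N", "CA", "CB", "CG", 1.328, 116.5, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", "CB", "CG", "CD", 1.249, 118.5, ("chi", 3, 0.0)),
        ("OE2", "O", "CB", "CG", "CD", 1.249, 118.5, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "N", "CB", "CG", "CD", 1.328, 116.5, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "C", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", "C", "CB", "CG", "CD", 1.520, 111.9, ("chi", 3, 0.0)),
        ("NZ", "N", "CG", "CD", "CE", 1.489, 111.7, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "C", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", "N", "CB", "CG", "CD", 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", "C", "CG", "CD", "NE", 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", "N", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "N", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


def heavy_atom_names(res_type: str) -> list[str]:
    """Backbone + side-chain heavy atom names expected for a complete residue."""
    rows = SIDE_CHAIN_ZMAT.get(res_type.upper())
    if rows is None:
        return list(BACKBONE_ATOMS)
    names = list(BACKBONE_ATOMS)
    if res_type.upper() not in ("GLY",):
        names.append("CB")
    names.extend(r[0] for r in rows)
    return names


def side_chain_atom_names(res_type: str) -> list[str]:
    rt = res_type.upper()
    rows = SIDE_CHAIN_ZMAT.get(rt, [])
    names = [] if rt == "GLY" else ["CB"]
    names.extend(r[0] for r in rows)
    return names


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: return D with |D-c| = length, angle(b,c,D) = angle and
    torsion(a,b,c,D) = dihedral."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone() -> dict[str, np.ndarray]:
    """Backbone (plus CB anchor) in a canonical local frame, CA at origin."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    ang = np.radians(111.0)
    c = 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, 150.0)
    cb = place_atom(c, n, ca, 1.530, 110.4, -122.6)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def build_residue_coords(res_type: str, chis) -> dict[str, np.ndarray]:
    """All heavy-atom coordinates of a residue at the target chi vector, in
    the canonical local frame (CA at origin).

    ``chis`` must supply one angle per chi torsion of the type (extra values
    ignored).  Raises KeyError for unknown types, ValueError on short chi
    vectors.
    """
    rt = res_type.upper()
    if rt not in SIDE_CHAIN_ZMAT:
        raise KeyError(f"no ideal-geometry template for residue type {res_type!r}")
    coords = build_backbone()
    if rt == "GLY":
        coords.pop("CB")
        return coords
    chis = list(chis)
    for name, _elem, ra, rb, rc, length, angle, dih in SIDE_CHAIN_ZMAT[rt]:
        if isinstance(dih, tuple):
            _, idx, offset = dih
            if idx > len(chis):
                raise ValueError(f"{rt} needs chi{idx} but only {len(chis)} given")
            torsion = float(chis[idx - 1]) + offset
        else:
            torsion = float(dih)
        coords[name] = place_atom(coords[ra], coords[rb], coords[rc],
                                  length, angle, torsion)
    return coords


def zmat_elements(res_type: str) -> dict[str, str]:
    elems = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for row in SIDE_CHAIN_ZMAT.get(res_type.upper(), []):
        elems[row[0]] = row[1]
    return elems
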