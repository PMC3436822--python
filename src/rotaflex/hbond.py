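"""Hydrogen-bond network analysis of binding-site side chains.

Only strong N/O...N/O hydrogen bonds are considered, detected with the
geometric criteria 1.5 A <= d(H...A) <= 2.7 A and theta(D-H...A) >= 90 deg
(all boundaries inclusive).  Polar hydrogens are placed deterministically at
ideal geometry: fixed positions on sp2 donors, staggered positions on Lys
NZ, and discrete-rotor optimisation for the Ser/Thr/Tyr hydroxyls (the rotor
position satisfying the most H-bonds wins, ties to the smallest torsion).
Water and ligand donors carry no explicit hydrogens; following the
virtual-hydrogen convention they donate whenever the heavy-atom distance to
the acceptor falls in a fixed window, with the angle treated as optimal.

Per binding-site residue the bonds are counted against three partner
entities (water, protein, ligand) in both forms, and the per-entity change
is expressed as conserved (equal counts, including zero/zero), gain or loss.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._restopo import place_atom
from .structio import Atom, ChemistryTables, LigandInstance, Residue, StructureModel

#: side chains counted in the H-bond statistics; Thr is toggled via criteria
ACTIVE_RESIDUES = frozenset({"ARG", "ASN", "ASP", "GLN", "GLU",
                             "HIS", "LYS", "SER", "TRP", "TYR"})


@dataclass(frozen=True)
class HBondCriteria:
    d_min: float = 1.5           # A, below this the pair is a clash
    d_max: float = 2.7           # A
    theta_min: float = 90.0      # deg
    water_heavy_max: float = 3.5  # A, virtual-hydrogen donors (water, ligand)
    water_heavy_min: float = 2.5
    include_thr: bool = True     # Thr hydroxyl counted alongside Ser/Tyr

    def active_types(self) -> frozenset:
        return ACTIVE_RESIDUES | {"THR"} if self.include_thr else ACTIVE_RESIDUES


@dataclass
class HBond:
    residue_key: tuple          # binding-site residue credited with the bond
    donor: str                  # "<label>:<atom>" description
    acceptor: str
    d_ha: float                 # A; heavy-atom distance for virtual donors
    theta: float                # deg; 180 (optimal) for virtual donors
    entity: str                 # water | protein | ligand
    virtual: bool = False


@dataclass
class HBondCounts:
    residue_key: tuple
    water: int = 0
    protein: int = 0
    ligand: int = 0

    def total(self) -> int:
        return self.water + self.protein + self.ligand


CONSERVED, GAIN, LOSS = "conserved", "gain", "loss"


@dataclass
class HBondDelta:
    residue_key: tuple
    water: str = CONSERVED
    protein: str = CONSERVED
    ligand: str = CONSERVED


# ---------------------------------------------------------------------------
# hydrogen placement

# donor atom -> (H base name, reference atoms / mode, count)
_SP2_PAIR = {  # two in-plane hydrogens built from (a, b, donor) at 0/180 deg
    ("ASN", "ND2"): ("HD2", ("CB", "CG")),
    ("GLN", "NE2"): ("HE2", ("CG", "CD")),
    ("ARG", "NH1"): ("HH1", ("NE", "CZ")),
    ("ARG", "NH2"): ("HH2", ("NE", "CZ")),
}
_BISECTOR = {  # single H opposite the two ring/chain neighbours
    ("ARG", "NE"): ("HE", ("CD", "CZ")),
    ("TRP", "NE1"): ("HE1", ("CD1", "CE2")),
    ("HIS", "ND1"): ("HD1", ("CG", "CE1")),
    ("HIS", "NE2"): ("HE2", ("CD2", "CE1")),
}
_ROTOR = {  # hydroxyl: single H on a rotatable bond, scanned in 30 deg steps
    ("SER", "OG"): ("HG", ("CA", "CB")),
    ("THR", "OG1"): ("HG1", ("CA", "CB")),
    ("TYR", "OH"): ("HH", ("CE1", "CZ")),
}

_NH_LENGTH = 1.01
_OH_LENGTH = 0.96
_ROTOR_STEP = 30.0


def _add_h(residue: Residue, name: str, pos: np.ndarray) -> None:
    residue.atoms.append(Atom(name=name, element="H", position=pos,
                              bfactor=15.0, occupancy=1.0))


def _rotor_positions(residue: Residue, donor: str, refs: tuple) -> list[np.ndarray]:
    a, b = (residue.atom(n) for n in refs)
    d = residue.atom(donor)
    if a is None or b is None or d is None:
        return []
    return [place_atom(a.position, b.position, d.position,
                       _OH_LENGTH, 109.5, tor)
            for tor in np.arange(0.0, 360.0, _ROTOR_STEP)]


def _place_fixed_hydrogens(residue: Residue) -> None:
    """All non-rotor polar hydrogens of one residue, ideal geometry."""
    rt = residue.type
    for (t, donor), (hname, refs) in _SP2_PAIR.items():
        if t != rt:
            continue
        a, b, d = (residue.atom(n) for n in (*refs, donor))
        if a is None or b is None or d is None:
            continue
        for i, tor in enumerate((0.0, 180.0), start=1):
            _add_h(residue, f"{hname}{i}",
                   place_atom(a.position, b.position, d.position,
                              _NH_LENGTH, 120.0, tor))
    for (t, donor), (hname, refs) in _BISECTOR.items():
        if t != rt:
            continue
        n1, n2, d = (residue.atom(n) for n in (*refs, donor))
        if n1 is None or n2 is None or d is None:
            continue
        u1 = n1.position - d.position
        u2 = n2.position - d.position
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        h_dir = -(u1 + u2)
        h_dir /= np.linalg.norm(h_dir)
        _add_h(residue, hname, d.position + _NH_LENGTH * h_dir)
    if rt == "LYS":
        cd, ce, nz = (residue.atom(n) for n in ("CD", "CE", "NZ"))
        if cd is not None and ce is not None and nz is not None:
            for i, tor in enumerate((180.0, 60.0, -60.0), start=1):
                _add_h(residue, f"HZ{i}",
                       place_atom(cd.position, ce.position, nz.position,
                                  _NH_LENGTH, 109.5, tor))


def place_polar_hydrogens(structure: StructureModel,
                          ligand: LigandInstance | None = None,
                          criteria: HBondCriteria | None = None,
                          tables: ChemistryTables | None = None) -> StructureModel:
    """Return a copy of the structure with side-chain polar hydrogens added.

    Carboxylates stay unprotonated.  Hydroxyl rotors are oriented to satisfy
    as many acceptors as possible; everything else is fixed ideal geometry.
    Existing hydrogens with the same names are replaced.
    """
    criteria = criteria or HBondCriteria()
    tables = tables or ChemistryTables.load()
    out = structure.copy()
    active = criteria.active_types()
    placed_names = {h for (hn, _refs) in
                    list(_SP2_PAIR.values()) + list(_BISECTOR.values()) + list(_ROTOR.values())
                    for h in (hn, hn + "1", hn + "2", hn + "3")}
    acceptors = _acceptor_list(out, ligand, criteria, tables)
    for res in out.residues:
        if res.type not in active:
            continue
        res.atoms = [a for a in res.atoms if a.name not in placed_names]
        _place_fixed_hydrogens(res)
        for (t, donor), (hname, refs) in _ROTOR.items():
            if t != res.type:
                continue
            cands = _rotor_positions(res, donor, refs)
            if not cands:
                continue
            d_atom = res.atom(donor)
            best_pos, best_n = cands[0], -1
            for pos in cands:
                n = 0
                for (apos, _entity, owner) in acceptors:
                    if owner == res.key:
                        continue
                    if _geometry_ok(d_atom.position, pos, apos, criteria):
                        n += 1
                if n > best_n:
                    best_n, best_pos = n, pos
            _add_h(res, hname, best_pos)
    return out


# ---------------------------------------------------------------------------
# detection

_BOUNDARY_TOL = 1e-9   # closed boundaries are inclusive up to float rounding


def _geometry_ok(d_pos, h_pos, a_pos, criteria: HBondCriteria) -> tuple | None:
    d_ha = float(np.linalg.norm(np.asarray(a_pos) - np.asarray(h_pos)))
    if not (criteria.d_min - _BOUNDARY_TOL <= d_ha <= criteria.d_max + _BOUNDARY_TOL):
        return None
    v1 = np.asarray(d_pos) - np.asarray(h_pos)
    v2 = np.asarray(a_pos) - np.asarray(h_pos)
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if theta < criteria.theta_min - _BOUNDARY_TOL:
        return None
    return d_ha, theta


def _role(res_type: str, atom_name: str, tables: ChemistryTables) -> str | None:
    return tables.donor_acceptor.get((res_type, atom_name))


def _attached_hydrogens(residue: Residue, donor: Atom) -> list[Atom]:
    return [a for a in residue.atoms
            if a.is_hydrogen and np.linalg.norm(a.position - donor.position) < 1.25]


def _acceptor_list(structure: StructureModel, ligand, criteria, tables):
    """(position, entity, owner_residue_key_or_None) for every N/O acceptor."""
    out = []
    active = criteria.active_types()
    for res in structure.residues:
        for a in res.heavy_atoms():
            if a.name in ("O", "OXT") and a.element == "O":
                out.append((a.position, "protein", res.key))
            elif res.type in active:
                role = _role(res.type, a.name, tables)
                if role in ("acceptor", "both"):
                    out.append((a.position, "protein", res.key))
    for w in structure.waters:
        out.append((w.position, "water", None))
    if ligand is not None:
        for a in ligand.heavy_atoms():
            if a.element in ("N", "O"):
                out.append((a.position, "ligand", None))
    return out


def _protein_donor_list(structure: StructureModel, criteria, tables):
    """(D atom, H atoms, owner residue) over side-chain donors."""
    out = []
    active = criteria.active_types()
    for res in structure.residues:
        if res.type not in active:
            continue
        for a in res.heavy_atoms():
            role = _role(res.type, a.name, tables)
            if role in ("donor", "both"):
                hs = _attached_hydrogens(res, a)
                if hs:
                    out.append((a, hs, res))
    return out


def detect_hbonds(structure: StructureModel,
                  ligand: LigandInstance | None = None,
                  site_residues=None,
                  criteria: HBondCriteria | None = None,
                  tables: ChemistryTables | None = None) -> list[HBond]:
    """Strong hydrogen bonds of binding-site side chains.

    ``structure`` must already carry polar hydrogens (see
    :func:`place_polar_hydrogens`).  Each returned bond is credited to one
    site residue; a side-chain/side-chain bond between two site residues
    yields one record per residue, which is what per-residue counting needs.
    """
    criteria = criteria or HBondCriteria()
    tables = tables or ChemistryTables.load()
    site = set(site_residues) if site_residues is not None else {
        r.key for r in structure.residues}
    active = criteria.active_types()
    acceptors = _acceptor_list(structure, ligand, criteria, tables)
    donors = _protein_donor_list(structure, criteria, tables)
    lig_atoms = ([a for a in ligand.heavy_atoms() if a.element in ("N", "O")]
                 if ligand is not None else [])

    bonds: list[HBond] = []
    for res in structure.residues:
        if res.key not in site or res.type not in active:
            continue
        label = res.label
        seen: set = set()

        def _emit(pair_id, bond):
            if pair_id in seen:
                return
            seen.add(pair_id)
            bonds.append(bond)

        # side-chain donor -> any acceptor
        for d_atom, hs, owner in donors:
            if owner.key != res.key:
                continue
            for h in hs:
                for apos, entity, akey in acceptors:
                    if akey == res.key:
                        continue
                    geo = _geometry_ok(d_atom.position, h.position, apos, criteria)
                    if geo is None:
                        continue
                    pid = (d_atom.name, entity, tuple(np.round(apos, 3)))
                    _emit(pid, HBond(res.key, f"{label}:{d_atom.name}",
                                     f"{entity}@{np.round(apos, 3)}",
                                     geo[0], geo[1], entity))
        # side-chain acceptor <- explicit protein donors of other residues
        for a in res.heavy_atoms():
            role = _role(res.type, a.name, tables)
            if role not in ("acceptor", "both"):
                continue
            for d_atom, hs, owner in donors:
                if owner.key == res.key:
                    continue
                for h in hs:
                    geo = _geometry_ok(d_atom.position, h.position,
                                       a.position, criteria)
                    if geo is None:
                        continue
                    pid = (a.name, "protein", tuple(np.round(d_atom.position, 3)))
                    _emit(pid, HBond(res.key, f"{owner.label}:{d_atom.name}",
                                     f"{label}:{a.name}", geo[0], geo[1],
                                     "protein"))
            # virtual donors: water and ligand N/O (no explicit hydrogens)
            for w in structure.waters:
                d = float(np.linalg.norm(w.position - a.position))
                if criteria.water_heavy_min <= d <= criteria.water_heavy_max:
                    pid = (a.name, "water", tuple(np.round(w.position, 3)))
                    _emit(pid, HBond(res.key, "water", f"{label}:{a.name}",
                                     d, 180.0, "water", virtual=True))
            for la in lig_atoms:
                d = float(np.linalg.norm(la.position - a.position))
                if criteria.water_heavy_min <= d <= criteria.water_heavy_max:
                    pid = (a.name, "ligand", tuple(np.round(la.position, 3)))
                    _emit(pid, HBond(res.key, f"ligand:{la.name}",
                                     f"{label}:{a.name}", d, 180.0,
                                     "ligand", virtual=True))
    return bonds


def count_hbonds(structure: StructureModel,
                 ligand: LigandInstance | None = None,
                 site_residues=None,
                 criteria: HBondCriteria | None = None,
                 tables: ChemistryTables | None = None) -> dict:
    """Per-residue bond counts by partner entity (water/protein/ligand)."""
    site = list(site_residues) if site_residues is not None else [
        r.key for r in structure.residues]
    counts = {key: HBondCounts(key) for key in site}
    for b in detect_hbonds(structure, ligand, site, criteria, tables):
        c = counts[b.residue_key]
        setattr(c, b.entity, getattr(c, b.entity) + 1)
    return counts


def hbond_delta(apo: HBondCounts, holo: HBondCounts) -> HBondDelta:
    """Per-entity conserved/gain/loss between the unbound and bound forms.

    Equal counts are conserved (a residue with no bonds in either form is
    conserved by definition); more bonds after binding is a gain, fewer a
    loss.
    """
    if apo.residue_key != holo.residue_key:
        raise ValueError("counts refer to different residues")

    def _call(a, h):
        if h > a:
            return GAIN
        if h < a:
            return LOSS
        return CONSERVED

    return HBondDelta(apo.residue_key,
                      water=_call(apo.water, holo.water),
                      protein=_call(apo.protein, holo.protein),
                      ligand=_call(apo.ligand, holo.ligand))


# ---------------------------------------------------------------------------
# Asn/Gln/His flip correction

_FLIP_SWAPS = {
    "ASN": [("OD1", "ND2")],
    "GLN": [("OE1", "NE2")],
    "HIS": [("ND1", "CD2"), ("CE1", "NE2")],
}
_TERMINAL_GROUP = {
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "HIS": ("ND1", "CD2", "CE1", "NE2"),
}

_CLASH_TOLERANCE = 0.4   # A inside the vdW sum before a contact is a clash


@dataclass
class FlipRecord:
    residue_key: tuple
    res_type: str
    flipped: bool
    clashes: tuple      # (original, flipped)
    hbonds: tuple       # (original, flipped)


def _flip(residue: Residue) -> Residue:
    r = residue.copy()
    for n1, n2 in _FLIP_SWAPS[r.type]:
        a1, a2 = r.atom(n1), r.atom(n2)
        if a1 is not None and a2 is not None:
            a1.position, a2.position = a2.position.copy(), a1.position.copy()
    return r


def _environment_atoms(structure, ligand, exclude_key, tables):
    env = []
    for res in structure.residues:
        if res.key == exclude_key:
            continue
        env.extend((a.position, tables.vdw_radius(a.element))
                   for a in res.heavy_atoms())
    for w in structure.waters:
        env.append((w.position, tables.vdw_radius("O")))
    if ligand is not None:
        env.extend((a.position, tables.vdw_radius(a.element))
                   for a in ligand.heavy_atoms())
    return env


def _orientation_score(structure, residue, ligand, criteria, tables):
    """(clash count, H-bond count) of one amide/imidazole orientation."""
    env = _environment_atoms(structure, ligand, residue.key, tables)
    clashes = 0
    for name in _TERMINAL_GROUP[residue.type]:
        a = residue.atom(name)
        if a is None:
            continue
        ra = tables.vdw_radius(a.element)
        for pos, rb in env:
            if np.linalg.norm(a.position - pos) < ra + rb - _CLASH_TOLERANCE:
                clashes += 1
    trial = structure.copy()
    for i, r in enumerate(trial.residues):
        if r.key == residue.key:
            trial.residues[i] = residue.copy()
            break
    trial = place_polar_hydrogens(trial, ligand, criteria, tables)
    n_bonds = len(detect_hbonds(trial, ligand, [residue.key], criteria, tables))
    return clashes, n_bonds


def correct_flips(structure: StructureModel,
                  ligand: LigandInstance | None = None,
                  criteria: HBondCriteria | None = None,
                  tables: ChemistryTables | None = None
                  ) -> tuple[StructureModel, list[FlipRecord]]:
    """Resolve the N/O (and His C/N) ambiguity of terminal amide groups.

    Both 180-degree orientations of each Asn/Gln amide and His imidazole are
    scored; the one with fewer heavy-atom clashes wins, ties going to the
    orientation with more satisfied H-bonds and then to the input.
    """
    criteria = criteria or HBondCriteria()
    tables = tables or ChemistryTables.load()
    out = structure.copy()
    report = []
    for i, res in enumerate(out.residues):
        if res.type not in _FLIP_SWAPS:
            continue
        flipped = _flip(res)
        c0, h0 = _orientation_score(out, res, ligand, criteria, tables)
        c1, h1 = _orientation_score(out, flipped, ligand, criteria, tables)
        do_flip = (c1, -h1) < (c0, -h0)
        if do_flip:
            out.residues[i] = flipped
        report.append(FlipRecord(res.key, res.type, do_flip, (c0, c1), (h0, h1)))
    return out, report
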