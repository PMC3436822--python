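"""Ground-truthed synthetic apo/holo pocket pairs.

The generator builds a spherical shell of ideal-geometry residues whose side
chains point at a small buried ligand, then plants controlled differences
between the two forms: genuine rotamer swaps, non-rotameric (NR) chi
offsets, sub-rotamer perturbations, a steric clash of chosen depth against
the transplanted ligand pose, and hydrogen-bond partners at exact
geometries.  Everything not planted is bit-identical between the forms, so
every pipeline output has a known expected value.

Geometric realism is deliberately sacrificed for verifiability: residues
are spatially disconnected (no peptide bonds), backbones are identical
between the forms (site backbone RMSD 0), and the ligand is an abstract
carbon scaffold plus whatever polar atoms the hydrogen-bond plants require.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import hbond as _hbond
from ._restopo import build_residue_coords, zmat_elements
from .rotamer import assign_rotamer, compute_chis, load_rotamer_library
from .structio import (Atom, ChemistryTables, LigandInstance, Residue,
                       StructureModel, write_pdb)

DEFAULT_ROSTER = ("SER", "LEU", "ASN", "LYS", "ASP", "PHE",
                  "THR", "GLN", "MET", "TYR", "ILE", "VAL")

_GATES = ("resolution", "identity", "overlap", "buffer", "ligand_size",
          "covalent", "site_size", "multi_chain", "burial", "missing_atoms",
          "extra_ligand", "site_rmsd")

_NR_OFFSET = 45.0       # deg per chi; outside every +/-30 admission window
_CONTACT_TARGET = 3.9   # A, closest side-chain/ligand approach (no overlap)


class InfeasiblePlanError(ValueError):
    pass


@dataclass(frozen=True)
class HBondPlant:
    """One planted hydrogen-bond partner for a pocket residue.

    ``entity`` 'ligand' plants an acceptor at exact (d_HA, theta) geometry
    against a fixed-geometry donor hydrogen (present in the holo form only,
    hence a gain when detectable).  ``entity`` 'water' plants a water oxygen
    at virtual-donor distance from an acceptor atom; ``presence`` selects
    which forms contain the water (both -> conserved, apo -> loss,
    holo -> gain).
    """
    residue_index: int
    entity: str = "ligand"          # ligand | water
    d_ha: float = 2.0               # A (ligand plants)
    theta: float = 180.0            # deg (ligand plants)
    heavy_distance: float = 2.9     # A (water plants)
    presence: str = "both"          # both | apo | holo (water plants)
    detectable: bool = True         # False for deliberate out-of-window plants


@dataclass(frozen=True)
class SyntheticPlan:
    n_residues: int = 12
    roster: tuple = DEFAULT_ROSTER
    flexible: tuple = ()            # residue indices given a real rotamer swap
    nr_apo: tuple = ()              # NR in apo, rotameric in holo (flexible)
    nr_holo: tuple = ()
    nr_both: tuple = ()             # NR in both forms (excluded observation)
    quality_fail: tuple = ()        # apo-NR residues with B=45 side chains
    small_shift: tuple = ()         # chi1 perturbed by ``small_shift_deg`` (rigid)
    small_shift_deg: float = 10.0
    clash_residue: int | None = None
    clash_depth: float = 0.5        # A of vdW overlap in the apo-bound form
    hbond_plants: tuple = ()
    resolution: float = 1.80
    ligand_code: str = "LIG"
    seed: int = 0
    violate: str | None = None      # one curation gate code, or None

    def __post_init__(self):
        idx = set(self.flexible) | set(self.nr_apo) | set(self.nr_holo) \
            | set(self.nr_both) | set(self.quality_fail) | set(self.small_shift)
        if any(i < 0 or i >= self.n_residues for i in idx):
            raise ValueError("planted residue index outside the roster")
        if self.clash_residue is not None:
            if self.clash_depth <= 0:
                raise ValueError("clash depth must be positive")
            moving = set(self.flexible) | set(self.nr_apo) | set(self.small_shift)
            if self.clash_residue not in moving:
                raise ValueError("clash residue must move between the forms "
                                 "(plant it as flexible, nr_apo or small_shift)")
        if self.violate is not None and self.violate not in _GATES:
            raise ValueError(f"unknown gate {self.violate!r}")


@dataclass
class GroundTruth:
    expected_call: dict = field(default_factory=dict)      # res key -> call
    expected_flexible_count: int = 0
    expected_apo_nr: int = 0
    expected_holo_nr: int = 0
    clash_residue: tuple | None = None
    expected_site_critical: bool = False
    expected_hbond_delta: dict = field(default_factory=dict)
    planted_bonds: dict = field(default_factory=dict)      # res key -> entity counts


# ---------------------------------------------------------------------------
# scaffolding helpers

def fibonacci_directions(n: int, hemisphere: bool = False) -> np.ndarray:
    """n deterministic quasi-uniform unit vectors (upper hemisphere only on
    request, for deliberately poor ligand burial)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    if hemisphere:
        z = (2.0 - (2.0 * i + 1.0) / n) / 2.0
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _base_ligand_coords() -> np.ndarray:
    ring = 1.40 * np.array([[np.cos(a), np.sin(a), 0.0]
                            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)])
    apex = np.array([[0.0, 0.0, 1.2], [0.0, 0.0, -1.2]])
    return np.vstack([ring, apex])


def build_residue(res_type: str, chis, rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None, chain_id: str = "A",
                  seq_num: int = 1, bfactor: float = 15.0) -> Residue:
    """Residue at an exact target chi vector, optionally moved rigidly.

    The measured chis of the result (via :func:`rotaflex.rotamer.compute_chis`)
    reproduce the targets to well under half a degree.
    """
    local = build_residue_coords(res_type, chis)
    elems = zmat_elements(res_type)
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    tr = np.zeros(3) if translation is None else np.asarray(translation, float)
    atoms = [Atom(name=n, element=elems[n], position=rot @ p + tr,
                  bfactor=bfactor, occupancy=1.0)
             for n, p in local.items()]
    return Residue(type=res_type.upper(), chain_id=chain_id, seq_num=seq_num,
                   atoms=atoms)


def _inward_rotation(direction: np.ndarray) -> np.ndarray:
    """Rotation taking the canonical CB direction onto -direction."""
    cb = build_residue_coords("ALA", [])["CB"]
    cb = cb / np.linalg.norm(cb)
    rot, _ = Rotation.align_vectors([-direction], [cb])
    return rot.as_matrix()


def _fit_radius(local_coords: dict, rot: np.ndarray, u: np.ndarray,
                lig_coords: np.ndarray) -> float:
    pts = np.array([rot @ p for p in local_coords.values()])
    for r in np.arange(3.0, 16.0, 0.05):
        d = np.sqrt(((pts + r * u - lig_coords[:, None, :]) ** 2).sum(axis=2))
        if d.min() >= _CONTACT_TARGET:
            return float(r)
    raise InfeasiblePlanError("cannot place residue around the ligand")


_DONOR_PREFS = {
    "ASN": ("ND2", ("HD21", "HD22")),
    "GLN": ("NE2", ("HE21", "HE22")),
    "LYS": ("NZ", ("HZ1", "HZ2", "HZ3")),
    "ARG": ("NE", ("HE",)),
    "TRP": ("NE1", ("HE1",)),
}


def _donor_sites(residue: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    """(donor position, hydrogen position) candidates of the residue's
    fixed-geometry donor, used to anchor planted acceptors."""
    probe = residue.copy()
    _hbond._place_fixed_hydrogens(probe)
    if residue.type not in _DONOR_PREFS:
        raise InfeasiblePlanError(
            f"{residue.type} has no fixed-geometry donor for an H-bond plant")
    dname, hnames = _DONOR_PREFS[residue.type]
    d = probe.atom(dname)
    out = [(d.position, probe.atom(h).position)
           for h in hnames if d is not None and probe.atom(h) is not None]
    if not out:
        raise InfeasiblePlanError(f"donor atoms missing on {residue.type}")
    return out


def _acceptor_site(residue: Residue, tables: ChemistryTables
                   ) -> tuple[np.ndarray, str]:
    for a in residue.side_chain_heavy_atoms():
        role = tables.donor_acceptor.get((residue.type, a.name))
        if role in ("acceptor", "both"):
            return a.position, a.name
    raise InfeasiblePlanError(f"{residue.type} has no side-chain acceptor")


def _planted_acceptor_position(d_pos, h_pos, d_ha: float, theta: float,
                               azimuth: float = 0.0) -> np.ndarray:
    """Acceptor at exact (d_HA, theta) geometry relative to a donor hydrogen;
    ``azimuth`` spins the off-axis component around the D-H axis."""
    u = h_pos - d_pos
    u = u / np.linalg.norm(u)
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    az = np.radians(azimuth)
    v_rot = np.cos(az) * v + np.sin(az) * w
    phi = np.radians(180.0 - theta)
    return h_pos + d_ha * (np.cos(phi) * u + np.sin(phi) * v_rot)


# ---------------------------------------------------------------------------
# pair generation

def generate_pair(plan: SyntheticPlan) -> tuple[StructureModel, StructureModel, GroundTruth]:
    """Build one apo/holo pocket pair with its complete ground truth."""
    lib = load_rotamer_library()
    tables = ChemistryTables.load()
    n = plan.n_residues
    types = [plan.roster[i % len(plan.roster)].upper() for i in range(n)]

    by_freq = {t: sorted(lib[t], key=lambda r: (-r.frequency, r.rotamer_id))
               for t in set(types)}
    holo_chis: dict[int, list] = {}
    apo_chis: dict[int, list] = {}
    truth = GroundTruth()
    for i, t in enumerate(types):
        rots = by_freq[t]
        base = list(rots[0].means)
        holo_chis[i] = list(base)
        apo_chis[i] = list(base)
        if i in plan.flexible:
            if len(rots) < 2:
                raise InfeasiblePlanError(f"{t} has a single library rotamer")
            apo_chis[i] = list(rots[1].means)
        if i in plan.nr_apo or i in plan.nr_both or i in plan.quality_fail:
            apo_chis[i] = [v + _NR_OFFSET for v in base]
        if i in plan.nr_holo or i in plan.nr_both:
            holo_chis[i] = [v + _NR_OFFSET for v in base]
        if i in plan.small_shift:
            # sub-rotamer perturbation on every torsion (alternating signs so
            # the per-bond movements compound instead of cancelling): the
            # residue stays in its rotamer (call: rigid) yet its tip moves
            apo_chis[i] = [v + plan.small_shift_deg * (-1.0) ** k
                           for k, v in enumerate(base)]

    lig_coords = _base_ligand_coords()
    dirs = fibonacci_directions(n, hemisphere=(plan.violate == "burial"))

    holo_residues, apo_residues = [], []
    for i, t in enumerate(types):
        rot = _inward_rotation(dirs[i])
        local_h = build_residue_coords(t, holo_chis[i])
        local_a = build_residue_coords(t, apo_chis[i])
        radius = max(_fit_radius(local_h, rot, dirs[i], lig_coords),
                     _fit_radius(local_a, rot, dirs[i], lig_coords))
        if plan.violate == "burial":
            radius += 1.5       # loosen the pocket: contacts remain, burial drops
        tr = radius * dirs[i]
        holo_residues.append(build_residue(t, holo_chis[i], rot, tr, "A", i + 1))
        apo_residues.append(build_residue(t, apo_chis[i], rot, tr, "A", i + 1))

    # verify planted NR offsets really fall outside every admission window
    for i in set(plan.nr_apo) | set(plan.nr_both) | set(plan.quality_fail):
        asn = assign_rotamer(compute_chis(apo_residues[i], tables), lib[types[i]])
        if not asn.is_nr:
            raise InfeasiblePlanError(f"NR offset landed in a rotamer for {types[i]}")

    lig_atoms = [Atom(name=f"C{k + 1}", element="C", position=p)
                 for k, p in enumerate(lig_coords)]
    apo_waters: list[Atom] = []
    holo_waters: list[Atom] = []

    # hydrogen-bond plants.  Planted partners must interact with their target
    # atom only: every candidate position is screened against all other polar
    # side-chain atoms (both forms) with a margin beyond the widest detection
    # window, so ground truth stays exact.
    polar_serial = 0
    moving = set(plan.flexible) | set(plan.nr_apo) | set(plan.nr_holo) \
        | set(plan.nr_both) | set(plan.quality_fail) | set(plan.small_shift)
    moving_keys = {holo_residues[i].key for i in moving}
    polar_avoid: list[tuple[np.ndarray, tuple]] = []   # (position, owner atom id)
    steric_avoid: list[tuple[np.ndarray, tuple, bool]] = []
    for res_list in (holo_residues, apo_residues):
        for res in res_list:
            for a in res.heavy_atoms():
                steric_avoid.append((a.position, res.key, res.key in moving_keys))
                if tables.donor_acceptor.get((res.type, a.name)):
                    polar_avoid.append((a.position, (res.key, a.name)))

    _POLAR_MARGIN = 3.8    # beyond every detection window (explicit + virtual)
    _STERIC_MARGIN = 3.3   # vdW-clear of residues that move between forms
    _COVALENT_MARGIN = 2.0  # merely covalent-safe for form-invariant residues
    #   (an overlap with an invariant residue contributes equally to both
    #    forms' WALL scores and cancels exactly in every delta)

    def _screened(candidates, target_ids, target_res_key) -> np.ndarray:
        best, best_margin = None, -np.inf
        for pos in candidates:
            margin = np.inf
            for p, aid in polar_avoid:
                if aid not in target_ids:
                    margin = min(margin, np.linalg.norm(pos - p) - _POLAR_MARGIN)
            for p, rkey, is_moving in steric_avoid:
                if rkey == target_res_key:
                    continue
                need = _STERIC_MARGIN if is_moving else _COVALENT_MARGIN
                margin = min(margin, np.linalg.norm(pos - p) - need)
            if margin > best_margin:
                best, best_margin = pos, margin
        if best_margin < 0.0:
            raise InfeasiblePlanError(
                "cannot place an H-bond plant clear of other atoms")
        return best

    for plant in plan.hbond_plants:
        res = holo_residues[plant.residue_index]
        key = res.key
        truth.expected_hbond_delta.setdefault(
            key, {"water": "conserved", "protein": "conserved",
                  "ligand": "conserved"})
        if plant.entity == "ligand":
            dname = _DONOR_PREFS.get(res.type, (None,))[0]
            sites = _donor_sites(res)
            # boundary-exact geometries get a hair's-width nudge toward the
            # intended side so float rounding cannot flip the verdict
            eps = 1e-6
            mid = 0.5 * (_hbond.HBondCriteria.d_min + _hbond.HBondCriteria.d_max)
            if plant.detectable:        # nudge toward the admission window
                d_ha = plant.d_ha + (eps if plant.d_ha < mid else -eps)
                theta = plant.theta + eps
            else:                       # nudge away from it
                d_ha = plant.d_ha + (-eps if plant.d_ha < mid else eps)
                theta = plant.theta - eps
            crit = _hbond.HBondCriteria()
            cands = []
            for d_pos, h_pos in sites:
                azimuths = (0.0,) if plant.theta == 180.0 else \
                    tuple(np.arange(0.0, 360.0, 15.0))
                for az in azimuths:
                    pos = _planted_acceptor_position(d_pos, h_pos, d_ha, theta, az)
                    # the verdict must come from the intended route for every
                    # donor hydrogen, not just the anchoring one
                    hits = sum(_hbond._geometry_ok(dp, hp, pos, crit) is not None
                               for dp, hp in sites)
                    if plant.detectable and hits < 1:
                        continue
                    if not plant.detectable and hits > 0:
                        continue
                    cands.append(pos)
            pos = _screened(cands, {(key, dname)}, key)
            polar_serial += 1
            lig_atoms.append(Atom(name=f"O{polar_serial}", element="O", position=pos))
            polar_avoid.append((pos, ("plant", polar_serial)))
            if plant.detectable:
                truth.expected_hbond_delta[key]["ligand"] = "gain"
                truth.planted_bonds.setdefault(key, {"ligand": 0, "water": 0})
                truth.planted_bonds[key]["ligand"] += 1
        elif plant.entity == "water":
            a_pos, a_name = _acceptor_site(res, tables)
            out_dir = a_pos - res.atom("CB").position
            out_dir = out_dir / np.linalg.norm(out_dir)
            cands = [a_pos + plant.heavy_distance * d
                     for d in [out_dir, *fibonacci_directions(32)]]
            pos = _screened(cands, {(key, a_name)}, key)
            w = Atom(name="O", element="O", position=pos)
            polar_avoid.append((pos, ("plant_w", len(polar_avoid))))
            if plant.presence in ("both", "apo"):
                apo_waters.append(w.copy())
            if plant.presence in ("both", "holo"):
                holo_waters.append(w.copy())
            if plant.detectable:
                call = {"both": "conserved", "apo": "loss", "holo": "gain"}[plant.presence]
                truth.expected_hbond_delta[key]["water"] = call
                truth.planted_bonds.setdefault(key, {"ligand": 0, "water": 0})
                truth.planted_bonds[key]["water"] += 1
        else:
            raise InfeasiblePlanError(f"unknown plant entity {plant.entity!r}")

    # steric clash plant: one extra ligand atom overlapping the apo conformer
    if plan.clash_residue is not None:
        i = plan.clash_residue
        pairs = [(a, apo_residues[i].atom(a.name))
                 for a in holo_residues[i].side_chain_heavy_atoms()]
        moved = sorted(((np.linalg.norm(h.position - a.position), h, a)
                        for h, a in pairs if a is not None), reverse=True,
                       key=lambda m: m[0])
        moved = [m for m in moved if m[0] >= plan.clash_depth + 0.1]
        if not moved:
            raise InfeasiblePlanError("apo/holo conformers too similar to "
                                      "plant the requested clash depth")
        # keep clear of every holo atom AND of other residues' apo atoms, so
        # the planted overlap is confined to the intended apo conformer
        avoid = [(at.position,
                  tables.vdw_radius(at.element) + tables.vdw_radius("C"))
                 for res in holo_residues for at in res.heavy_atoms()]
        avoid += [(at.position,
                   tables.vdw_radius(at.element) + tables.vdw_radius("C"))
                  for j, res in enumerate(apo_residues) if j != i
                  for at in res.heavy_atoms()]

        def _clearance(pos):
            return min(np.linalg.norm(pos - p) - r2 for p, r2 in avoid)

        # the atom must overlap one apo-conformer atom by ``clash_depth``
        # while staying outside every avoided vdW sphere; scan anchor atoms
        # (by displacement) and directions around each
        best_pos, best_clear = None, -np.inf
        for _sep, h_atom, a_atom in moved:
            r_sum = tables.vdw_radius(a_atom.element) + tables.vdw_radius("C")
            d0 = a_atom.position - h_atom.position
            d0 = d0 / np.linalg.norm(d0)
            for cand in [d0, *fibonacci_directions(64)]:
                pos = a_atom.position + (r_sum - plan.clash_depth) * cand
                c = _clearance(pos)
                if c > best_clear:
                    best_pos, best_clear = pos, c
            if best_clear >= 0.0:
                break
        if best_clear < 0.0:
            raise InfeasiblePlanError("clash plant overlaps the holo form")
        lig_atoms.append(Atom(name="CX", element="C", position=best_pos))
        truth.clash_residue = holo_residues[i].key
        truth.expected_site_critical = True

    ligand = LigandInstance(het_code=plan.ligand_code, chain_id="A",
                            seq_num=n + 1, atoms=lig_atoms)

    holo = StructureModel(pdb_id="HOLO", resolution=plan.resolution,
                          residues=holo_residues, ligands=[ligand],
                          waters=holo_waters)
    apo = StructureModel(pdb_id="APO_", resolution=plan.resolution,
                         residues=apo_residues, waters=apo_waters)

    # expected flexibility calls
    for i, res in enumerate(holo_residues):
        if i in plan.quality_fail:
            call = "excluded_quality"
        elif i in plan.nr_both:
            call = "excluded_NR_NR"
        elif i in plan.flexible or i in plan.nr_apo or i in plan.nr_holo:
            call = "flexible"
        else:
            call = "rigid"
        truth.expected_call[res.key] = call
    truth.expected_flexible_count = sum(
        1 for c in truth.expected_call.values() if c == "flexible")
    truth.expected_apo_nr = len(set(plan.nr_apo) | set(plan.nr_both))
    truth.expected_holo_nr = len(set(plan.nr_holo) | set(plan.nr_both))

    _apply_violation(plan, apo, holo, ligand, types, dirs)

    for res_list in (apo.residues, holo.residues):
        for res in res_list:
            for a in res.atoms:
                a.bfactor = 15.0
    for i in plan.quality_fail:     # poor-density plant: apo side chain only
        for a in apo.residues[i].side_chain_heavy_atoms():
            a.bfactor = 45.0
    return apo, holo, truth


def _apply_violation(plan, apo, holo, ligand, types, dirs) -> None:
    v = plan.violate
    if v is None or v == "burial":      # burial handled via hemisphere layout
        return
    n = plan.n_residues
    if v == "resolution":
        apo.resolution = 2.60
    elif v == "identity":
        i = 0
        other = next(t for t in DEFAULT_ROSTER if t != types[i])
        old = apo.residues[i]
        ca = old.atom("CA").position
        apo.residues[i] = build_residue(
            other, load_rotamer_library()[other][0].means,
            _inward_rotation(dirs[i]), ca, "A", old.seq_num)
    elif v == "overlap":
        far = 30.0
        extra_dirs = fibonacci_directions(4)
        for k in range(4):
            tr = far * extra_dirs[k]
            apo.residues.insert(k, build_residue(
                "GLY", [], np.eye(3), tr + np.array([0, 0, 40.0]), "A", -(4 - k)))
            holo.residues.append(build_residue(
                "GLY", [], np.eye(3), tr + np.array([0, 0, -40.0]), "A", n + 10 + k))
    elif v == "buffer":
        ligand.het_code = "SO4"
    elif v == "ligand_size":
        del ligand.atoms[4:]
    elif v == "covalent":
        cb = holo.residues[0].atom("CB")
        ligand.atoms.append(Atom(name="CV", element="C",
                                 position=cb.position + np.array([0.0, 0.0, 1.0])))
    elif v == "site_size":
        shift = np.array([0.0, 0.0, 30.0])
        for a in ligand.atoms:
            a.position = a.position + shift
    elif v == "multi_chain":
        for res_list in (apo.residues, holo.residues):
            for res in res_list:
                if res.seq_num > n // 2:
                    res.chain_id = "B"
    elif v == "missing_atoms":
        res = apo.residues[0]
        tip = res.side_chain_heavy_atoms()[-1]
        res.atoms = [a for a in res.atoms if a.name != tip.name]
    elif v == "extra_ligand":
        atoms = []
        for k in range(min(11, n)):
            cb = holo.residues[k].atom("CB").position
            pos = cb + 2.5 * (-dirs[k])
            atoms.append(Atom(name=f"C{k + 1}", element="C", position=pos))
        holo.ligands.append(LigandInstance(het_code="EXL", chain_id="A",
                                           seq_num=n + 2, atoms=atoms))
    elif v == "site_rmsd":
        for j, res in enumerate(apo.residues):
            shift = np.array([0.0, 0.0, 4.0 if j % 2 == 0 else -4.0])
            for a in res.atoms:
                a.position = a.position + shift


# ---------------------------------------------------------------------------
# ensembles

def generate_ensemble(n_pairs: int, distribution=("poisson", 1.5),
                      seed: int = 0, n_residues: int = 12
                      ) -> list[tuple[StructureModel, StructureModel, GroundTruth]]:
    """n independent pocket pairs whose planted flexible-residue counts are
    drawn from the stated distribution (reproducible under the seed)."""
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(seed)
    kind, param = distribution
    out = []
    for i in range(n_pairs):
        if kind == "poisson":
            k = int(min(rng.poisson(param), n_residues))
        elif kind == "fixed":
            k = int(param)
        else:
            raise ValueError(f"unknown distribution {kind!r}")
        idx = tuple(sorted(rng.choice(n_residues, size=k, replace=False))) if k else ()
        plan = SyntheticPlan(n_residues=n_residues, flexible=idx,
                             seed=int((seed * 131071 + i) % (2 ** 31)))
        apo, holo, truth = generate_pair(plan)
        apo.pdb_id = f"A{i:03d}"
        holo.pdb_id = f"H{i:03d}"
        out.append((apo, holo, truth))
    return out


def write_pair(apo: StructureModel, holo: StructureModel, truth: GroundTruth,
               out_dir) -> None:
    """Dump a generated pair as PDB files plus a ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(apo, out_dir / "apo.pdb")
    write_pdb(holo, out_dir / "holo.pdb")
    payload = {
        "expected_call": {"".join(map(str, k)): v
                          for k, v in truth.expected_call.items()},
        "expected_flexible_count": truth.expected_flexible_count,
        "expected_site_critical": truth.expected_site_critical,
        "expected_apo_nr": truth.expected_apo_nr,
        "expected_holo_nr": truth.expected_holo_nr,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
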