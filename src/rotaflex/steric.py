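"""Steric feasibility of the ligand pose in the unbound protein.

The holo ligand is transplanted into the apo structure after superposing the
binding-site backbones ("apo-bound" form).  Atomic overlap between the
ligand and the protein is scored with the WALL penalty: for every
ligand-protein heavy-atom pair closer than the sum of van der Waals radii,

    wall(r_ij) = K_wall * ((r_i + r_j - r_ij) / (r_i + r_j))^p      (p = 4)

and zero otherwise.  The site-level difference WALL(apo-bound) - WALL(holo)
measures how much worse the unbound side-chain conformations accommodate the
ligand; above the site threshold the pose is no longer acceptable and the
residues whose individual contributions exceed the residue threshold are the
sterically critical ones.  Quadratic and hard-step penalty forms are
available since the thresholds are only meaningful relative to the form.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import superpose
from .rotamer import ChiVector, max_delta_chi
from .structio import BACKBONE_ATOMS, ChemistryTables, LigandInstance, StructureModel

MINIMAL_ROTATION_CUTOFF = 15.0   # degrees, strict upper bound


@dataclass(frozen=True)
class WallParameters:
    k_wall: float = 1.0e6
    site_threshold: float = 150.0
    residue_threshold: float = 25.0
    form: str = "quartic"        # quartic | quadratic | step

    def __post_init__(self):
        if self.k_wall <= 0 or self.site_threshold <= 0 or self.residue_threshold <= 0:
            raise ValueError("WALL constants must be positive")
        if self.form not in ("quartic", "quadratic", "step"):
            raise ValueError(f"unknown WALL form {self.form!r}")


@dataclass
class WallScore:
    total: float
    per_residue: dict = field(default_factory=dict)   # residue key -> contribution
    clashes: list = field(default_factory=list)       # (res key, atom, lig atom, d, r_sum)


def _penalty(overlap_rel: np.ndarray, params: WallParameters) -> np.ndarray:
    if params.form == "quartic":
        return params.k_wall * overlap_rel ** 4
    if params.form == "quadratic":
        return params.k_wall * overlap_rel ** 2
    return np.full_like(overlap_rel, params.k_wall)      # hard step


def wall_potential(residues, ligand_atoms, tables: ChemistryTables | None = None,
                   params: WallParameters | None = None) -> WallScore:
    """WALL score of a ligand against protein residues (heavy atoms only).

    ``residues`` is an iterable of :class:`~rotaflex.structio.Residue`;
    hydrogens are ignored on both sides.  Coincident atoms (r_ij ~ 0) raise.
    """
    tables = tables or ChemistryTables.load()
    params = params or WallParameters()
    prot = [(r.key, a) for r in residues for a in r.heavy_atoms()]
    lig = [a for a in ligand_atoms if not a.is_hydrogen]
    score = WallScore(0.0)
    if not prot or not lig:
        return score
    pc = np.array([a.position for _, a in prot])
    pr = np.array([tables.vdw_radius(a.element) for _, a in prot])
    lc = np.array([a.position for a in lig])
    lr = np.array([tables.vdw_radius(a.element) for a in lig])
    d = np.sqrt(((pc[:, None, :] - lc[None, :, :]) ** 2).sum(axis=2))
    if np.any(d < 1e-6):
        raise ValueError("coincident ligand/protein atoms in WALL evaluation")
    rsum = pr[:, None] + lr[None, :]
    overlap = rsum - d
    ii, jj = np.nonzero(overlap > 0.0)
    if ii.size == 0:
        return score
    pen = _penalty(overlap[ii, jj] / rsum[ii, jj], params)
    for k in range(ii.size):
        i, j = int(ii[k]), int(jj[k])
        key, atom = prot[i]
        score.per_residue[key] = score.per_residue.get(key, 0.0) + float(pen[k])
        score.clashes.append((key, atom.name, lig[j].name,
                              float(d[i, j]), float(rsum[i, j])))
    score.total = float(sum(score.per_residue.values()))
    return score


# ---------------------------------------------------------------------------
# apo-bound construction

def site_backbone_coords(structure: StructureModel, residue_keys) -> np.ndarray:
    coords = []
    for key in residue_keys:
        res = structure.residue(key)
        if res is None:
            raise ValueError(f"residue {key} missing from structure")
        for name in BACKBONE_ATOMS:
            at = res.atom(name)
            if at is not None:
                coords.append(at.position)
    return np.array(coords).reshape(-1, 3)


def build_apo_bound(pair) -> tuple[StructureModel, "object"]:
    """Transplant the holo ligand into the apo frame.

    The holo->apo transform comes from superposing the binding-site backbone
    (N, CA, C, O of corresponding residues).  Returns the apo structure with
    the transplanted ligand appended, plus the transform used.
    """
    site_holo = list(pair.binding_site)
    site_apo = [pair.correspondence[k] for k in site_holo]
    holo_bb = site_backbone_coords(pair.holo, site_holo)
    apo_bb = site_backbone_coords(pair.apo, site_apo)
    if holo_bb.shape != apo_bb.shape:
        raise ValueError("apo/holo site backbones do not match atom-for-atom")
    transform, _ = superpose(apo_bb, holo_bb)
    apo_bound = pair.apo.copy()
    lig = pair.ligand.copy()
    for a in lig.atoms:
        a.position = transform.apply(a.position)
    apo_bound.ligands.append(lig)
    return apo_bound, transform


def delta_wall(pair, tables: ChemistryTables | None = None,
               params: WallParameters | None = None) -> tuple[float, dict]:
    """Site and per-residue WALL(apo-bound) - WALL(holo).

    Per-residue deltas are keyed by the holo residue; positive values mean
    the apo conformation clashes more with the ligand pose than holo does.
    """
    tables = tables or ChemistryTables.load()
    params = params or WallParameters()
    apo_bound, _ = build_apo_bound(pair)
    lig = apo_bound.ligands[-1]
    apo_score = wall_potential(apo_bound.residues, lig.atoms, tables, params)
    holo_score = wall_potential(pair.holo.residues, pair.ligand.atoms, tables, params)
    apo_to_holo = {v: k for k, v in pair.correspondence.items()}
    per_res: dict = {}
    for key, val in holo_score.per_residue.items():
        per_res[key] = per_res.get(key, 0.0) - val
    for key, val in apo_score.per_residue.items():
        hkey = apo_to_holo.get(key, key)
        per_res[hkey] = per_res.get(hkey, 0.0) + val
    site_delta = apo_score.total - holo_score.total
    return site_delta, per_res


# ---------------------------------------------------------------------------
# criticality and the minimal-rotation question

@dataclass
class CriticalityRecord:
    residue_key: tuple
    delta_wall: float
    critical: bool
    flexibility_call: str | None = None
    minimal_rotation: bool | None = None   # defined only for critical residues


def minimal_rotation_test(apo_chis: ChiVector, holo_chis: ChiVector) -> bool:
    """True when the largest circular chi change is strictly below 15 deg."""
    return max_delta_chi(apo_chis, holo_chis) < MINIMAL_ROTATION_CUTOFF


def classify_criticality(site_delta: float, per_residue_delta: dict,
                         flexibility_calls: dict | None = None,
                         chi_pairs: dict | None = None,
                         params: WallParameters | None = None
                         ) -> tuple[bool, list[CriticalityRecord]]:
    """Flag the site and the individual residues whose apo conformations
    sterically exclude the ligand pose.

    ``flexibility_calls`` maps residue key -> call string and ``chi_pairs``
    maps residue key -> (apo ChiVector, holo ChiVector); both optional.
    """
    params = params or WallParameters()
    site_critical = site_delta > params.site_threshold
    records = []
    for key in sorted(per_residue_delta):
        dv = per_residue_delta[key]
        crit = dv > params.residue_threshold
        call = flexibility_calls.get(key) if flexibility_calls else None
        minrot = None
        if crit and chi_pairs and key in chi_pairs:
            apo_chi, holo_chi = chi_pairs[key]
            minrot = minimal_rotation_test(apo_chi, holo_chi)
        records.append(CriticalityRecord(key, float(dv), crit, call, minrot))
    return site_critical, records
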