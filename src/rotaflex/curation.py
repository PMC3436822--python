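"""Apo/holo pair curation.

A database entry is a pair of structures of the same protein, one bound to a
subject ligand (holo) and one without it (apo).  ``validate_pair`` applies
the curation gates in a fixed order and reports the first failure as a
reason code, so verdicts are reproducible:

    resolution -> identity -> overlap -> buffer -> ligand_size -> covalent
    -> site_size -> multi_chain -> burial -> missing_atoms -> extra_ligand
    -> site_rmsd

Rejection is a verdict, not an error; an accepted pair carries the binding
site, the residue correspondence and the ligand burial fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from . import geometry
from ._restopo import THREE_TO_ONE
from .geometry import DEFAULT_PROBE, ContactSet
from .structio import (ChemistryTables, LigandInstance, StructureModel,
                       is_buffer_ligand)

ACCEPTED = "accepted"


@dataclass(frozen=True)
class PairingCriteria:
    max_resolution: float = 2.50       # A, both forms
    min_identity: float = 1.00         # over aligned columns
    min_overlap: float = 0.80          # aligned fraction of either length
    max_extra_contact_diff: int = 10   # residue contacts of non-subject ligands
    min_ligand_heavy_atoms: int = 5
    min_contacted_residues: int = 5
    min_fc: float = 0.70               # burial fraction
    max_site_rmsd: float = 2.50        # A, site backbone after superposition
    fc_convention: str = "buried"
    strict_ligand_size: bool = False   # True: "five atoms or less" reads as >= 6


@dataclass
class AlignmentResult:
    identity: float
    overlap_apo: float
    overlap_holo: float
    correspondence: dict       # holo residue key -> apo residue key

    @property
    def overlap(self) -> float:
        return max(self.overlap_apo, self.overlap_holo)


@dataclass
class ApoHoloPair:
    apo: StructureModel
    holo: StructureModel
    ligand: LigandInstance
    correspondence: dict = field(default_factory=dict)
    binding_site: list = field(default_factory=list)   # holo residue keys
    fc: float | None = None
    site_rmsd: float | None = None
    verdict: str = ACCEPTED
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.verdict == ACCEPTED

    @property
    def pair_id(self) -> str:
        return f"{self.apo.pdb_id}-{self.holo.pdb_id}-{self.ligand.het_code}"


# ---------------------------------------------------------------------------
# sequence pairing

def _chain_sequences(structure: StructureModel) -> dict:
    out = {}
    for chain_id, residues in structure.chains.items():
        ordered = sorted(residues, key=lambda r: (r.seq_num, r.icode))
        seq = "".join(THREE_TO_ONE.get(r.type, "X") for r in ordered)
        out[chain_id] = (seq, ordered)
    return out


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -0.5
    # terminal extensions (tags, domain-boundary choices) are not penalised
    try:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    except AttributeError:      # older biopython naming
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    return al


def align_sequences(apo: StructureModel, holo: StructureModel) -> AlignmentResult:
    """Global (Needleman-Wunsch) pairing of the two structures' sequences.

    Chains sharing an id are aligned against each other; identity is the
    fraction of matching aligned columns, overlap the aligned fraction of
    each total length ("either" length may satisfy the overlap gate).  The
    correspondence maps matched holo residues onto apo residues.
    """
    apo_seqs = _chain_sequences(apo)
    holo_seqs = _chain_sequences(holo)
    shared = sorted(set(apo_seqs) & set(holo_seqs))
    if not shared:
        raise ValueError("no chain ids in common between apo and holo")
    al = _aligner()
    matches = 0
    aligned_cols = 0
    correspondence: dict = {}
    for cid in shared:
        seq_a, res_a = apo_seqs[cid]
        seq_h, res_h = holo_seqs[cid]
        if not seq_a or not seq_h:
            continue
        aln = al.align(seq_a, seq_h)[0]
        for (a_start, a_end), (h_start, h_end) in zip(*aln.aligned):
            for k in range(a_end - a_start):
                ra = res_a[a_start + k]
                rh = res_h[h_start + k]
                aligned_cols += 1
                if ra.type == rh.type:
                    matches += 1
                    correspondence[rh.key] = ra.key
    if aligned_cols == 0:
        raise ValueError("no alignable residues between apo and holo")
    len_a = sum(len(s) for s, _ in apo_seqs.values())
    len_h = sum(len(s) for s, _ in holo_seqs.values())
    return AlignmentResult(identity=matches / aligned_cols,
                           overlap_apo=aligned_cols / len_a,
                           overlap_holo=aligned_cols / len_h,
                           correspondence=correspondence)


# ---------------------------------------------------------------------------
# binding site

def contacts(structure: StructureModel, ligand: LigandInstance,
             tables: ChemistryTables | None = None,
             probe: float = DEFAULT_PROBE) -> ContactSet:
    """Probe-mediated atomic contacts between a ligand and the protein."""
    tables = tables or ChemistryTables.load()
    prot = structure.protein_heavy_atoms()
    lig = ligand.heavy_atoms()
    cs = ContactSet()
    if not prot or not lig:
        return cs
    pc = np.array([a.position for _, a in prot])
    pr = np.array([tables.vdw_radius(a.element) for _, a in prot])
    lc = np.array([a.position for a in lig])
    lr = np.array([tables.vdw_radius(a.element) for a in lig])
    for i, j in geometry.contact_pairs(pc, pr, lc, lr, probe):
        res, atom = prot[i]
        cs.pairs.append((res.key, atom.name, int(j)))
        cs.per_residue[res.key] = cs.per_residue.get(res.key, 0) + 1
    return cs


def define_binding_site(holo: StructureModel, ligand: LigandInstance,
                        tables: ChemistryTables | None = None,
                        probe: float = DEFAULT_PROBE) -> list:
    """Residues with at least one atom in contact with a ligand atom."""
    return contacts(holo, ligand, tables, probe).residues


def fraction_in_contact(ligand: LigandInstance, complex_structure: StructureModel,
                        tables: ChemistryTables | None = None,
                        probe: float = DEFAULT_PROBE,
                        n_points: int = geometry.DEFAULT_SASA_POINTS,
                        convention: str = "buried") -> float:
    """Burial fraction Fc of the ligand, from free vs in-complex SASA.

    The free-ligand surface uses the identical ligand conformation; the
    bound surface is computed against the protein heavy atoms (waters are
    solvent and do not occlude).
    """
    tables = tables or ChemistryTables.load()
    lig_atoms = ligand.heavy_atoms()
    lc = np.array([a.position for a in lig_atoms])
    lr = np.array([tables.vdw_radius(a.element) for a in lig_atoms])
    free = geometry.sasa(lc, lr, probe, n_points)
    prot = complex_structure.protein_heavy_atoms()
    pc = np.array([a.position for _, a in prot]).reshape(-1, 3)
    pr = np.array([tables.vdw_radius(a.element) for _, a in prot])
    allc = np.vstack([lc, pc]) if pc.size else lc
    allr = np.concatenate([lr, pr]) if pr.size else lr
    bound = geometry.sasa(allc, allr, probe, n_points)
    bound_lig = float(bound.per_atom[:len(lig_atoms)].sum())
    return geometry.fraction_buried(free.total, bound_lig, convention)


# ---------------------------------------------------------------------------
# validation

def _covalently_bound(holo: StructureModel, ligand: LigandInstance,
                      tables: ChemistryTables) -> bool:
    prot = holo.protein_heavy_atoms()
    if not prot:
        return False
    pc = np.array([a.position for _, a in prot])
    pr = np.array([tables.covalent_radius(a.element) for _, a in prot])
    for la in ligand.heavy_atoms():
        cut = pr + tables.covalent_radius(la.element) + 0.4
        d = np.sqrt(((pc - la.position) ** 2).sum(axis=1))
        if np.any(d <= cut):
            return True
    return False


def _extra_ligand_mismatch(pair_apo: StructureModel, pair_holo: StructureModel,
                           subject: LigandInstance, tables: ChemistryTables,
                           max_diff: int) -> bool:
    """True when any non-subject ligand differs by more than ``max_diff``
    residue-level contacts between the forms (including absence)."""

    def _counts(structure, skip_key=None):
        out = {}
        for lig in structure.ligands:
            if skip_key is not None and lig.key == skip_key:
                continue
            cs = contacts(structure, lig, tables)
            out[lig.het_code] = out.get(lig.het_code, 0) + len(cs.per_residue)
        return out

    holo_counts = _counts(pair_holo, skip_key=subject.key)
    apo_counts = _counts(pair_apo)
    for code in set(holo_counts) | set(apo_counts):
        if abs(holo_counts.get(code, 0) - apo_counts.get(code, 0)) > max_diff:
            return True
    return False


def validate_pair(apo: StructureModel, holo: StructureModel,
                  ligand: LigandInstance,
                  criteria: PairingCriteria | None = None,
                  tables: ChemistryTables | None = None) -> ApoHoloPair:
    """Run the curation gates in order; the first failure is the verdict."""
    criteria = criteria or PairingCriteria()
    tables = tables or ChemistryTables.load()
    pair = ApoHoloPair(apo=apo, holo=holo, ligand=ligand)

    def reject(code: str) -> ApoHoloPair:
        pair.verdict = "rejected"
        pair.reason = code
        return pair

    for st in (apo, holo):
        if st.resolution is not None and st.resolution > criteria.max_resolution:
            return reject("resolution")

    try:
        aln = align_sequences(apo, holo)
    except ValueError:
        return reject("identity")
    pair.correspondence = aln.correspondence
    if aln.identity < criteria.min_identity:
        return reject("identity")
    if aln.overlap < criteria.min_overlap:
        return reject("overlap")

    if is_buffer_ligand(ligand.het_code, tables):
        return reject("buffer")

    min_atoms = criteria.min_ligand_heavy_atoms + (1 if criteria.strict_ligand_size else 0)
    if len(ligand.heavy_atoms()) < min_atoms:
        return reject("ligand_size")

    if _covalently_bound(holo, ligand, tables):
        return reject("covalent")

    site = define_binding_site(holo, ligand, tables)
    pair.binding_site = site
    if len(site) < criteria.min_contacted_residues:
        return reject("site_size")
    if len({k[0] for k in site}) > 1:
        return reject("multi_chain")

    pair.fc = fraction_in_contact(ligand, holo, tables,
                                  convention=criteria.fc_convention)
    if pair.fc < criteria.min_fc:
        return reject("burial")

    for key in site:
        hres = holo.residue(key)
        akey = aln.correspondence.get(key)
        ares = apo.residue(akey) if akey is not None else None
        if ares is None:
            return reject("missing_atoms")
        if hres.missing_side_chain_atoms() or ares.missing_side_chain_atoms():
            return reject("missing_atoms")
        if not hres.is_complete or not ares.is_complete:
            return reject("missing_atoms")

    if _extra_ligand_mismatch(apo, holo, ligand, tables,
                              criteria.max_extra_contact_diff):
        return reject("extra_ligand")

    from .steric import site_backbone_coords   # local import to avoid a cycle
    holo_bb = site_backbone_coords(holo, site)
    apo_bb = site_backbone_coords(apo, [aln.correspondence[k] for k in site])
    if holo_bb.shape != apo_bb.shape:
        return reject("missing_atoms")
    _, pair.site_rmsd = geometry.superpose(holo_bb, apo_bb)
    if pair.site_rmsd > criteria.max_site_rmsd:
        return reject("site_rmsd")

    return pair


# ---------------------------------------------------------------------------
# redundancy reduction

@dataclass
class EntryGroup:
    """Pairs sharing a (user-supplied) domain label and ligand code."""
    domain: str
    ligand_code: str
    members: list = field(default_factory=list)   # (pair_id, fc)

    def __post_init__(self):
        if not self.members:
            raise ValueError("entry group must have at least one member")


def select_representative(group: EntryGroup) -> str:
    """Member with the largest burial fraction; ties go to the smaller id."""
    return sorted(group.members, key=lambda m: (-m[1], m[0]))[0][0]


def group_entries(pairs_with_labels) -> list[EntryGroup]:
    """Group (pair_id, domain, ligand_code, fc) rows into entry groups."""
    grouped: dict = {}
    for pair_id, domain, lig_code, fc in pairs_with_labels:
        grouped.setdefault((domain, lig_code), []).append((pair_id, fc))
    return [EntryGroup(domain=d, ligand_code=c, members=m)
            for (d, c), m in sorted(grouped.items())]
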