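"""End-to-end apo/holo analysis driver.

``analyze_pair`` runs one validated pair through rotamer assignment, the
steric (WALL) comparison of the apo-bound form and the hydrogen-bond
network accounting, producing one flat record per analysed binding-site
residue.  ``analyze_ensemble`` maps this over many pairs and aggregates the
study-level summaries; ``write_report`` emits deterministic TSV tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation, geometry, hbond, rotamer, stats_report, steric
from ._restopo import side_chain_atom_names
from .curation import ApoHoloPair, PairingCriteria
from .hbond import HBondCriteria
from .steric import WallParameters
from .structio import ChemistryTables, LigandInstance, StructureModel


@dataclass
class PipelineConfig:
    criteria: PairingCriteria = field(default_factory=PairingCriteria)
    wall: WallParameters = field(default_factory=WallParameters)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    validate: bool = True        # False: trust the pair, skip curation gates
    correct_flips: bool = False  # amide/imidazole flip correction before H-bonds
    compute_sasa: bool = True
    compute_hbonds: bool = True
    compute_steric: bool = True


@dataclass
class PairResult:
    pair: ApoHoloPair
    records: list = field(default_factory=list)      # one dict per site residue
    site_delta_wall: float | None = None
    site_critical: bool | None = None

    @property
    def accepted(self) -> bool:
        return self.pair.accepted

    def flexible_count(self) -> int:
        return sum(1 for r in self.records if r["call"] == rotamer.FLEXIBLE)


def _trusting_pair(apo, holo, ligand, tables) -> ApoHoloPair:
    """Pair assembly without the curation gates (synthetic/known-good input)."""
    aln = curation.align_sequences(apo, holo)
    site = curation.define_binding_site(holo, ligand, tables)
    return ApoHoloPair(apo=apo, holo=holo, ligand=ligand,
                       correspondence=aln.correspondence, binding_site=site)


_REFERENCE_SASA_CACHE: dict = {}


def reference_side_chain_sasa(res_type: str,
                              tables: ChemistryTables | None = None) -> float:
    """Side-chain SASA of the isolated extended residue, the normalisation
    reference for per-residue accessibility (same engine, same radii)."""
    rt = res_type.upper()
    if rt in _REFERENCE_SASA_CACHE:
        return _REFERENCE_SASA_CACHE[rt]
    from .synthetic import build_residue
    tables = tables or ChemistryTables.load()
    n_chi = tables.n_chis(rt)
    res = build_residue(rt, [180.0] * n_chi)
    atoms = res.heavy_atoms()
    coords = np.array([a.position for a in atoms])
    radii = np.array([tables.vdw_radius(a.element) for a in atoms])
    rep = geometry.sasa(coords, radii)
    side = set(side_chain_atom_names(rt))
    val = float(sum(area for a, area in zip(atoms, rep.per_atom)
                    if a.name in side))
    _REFERENCE_SASA_CACHE[rt] = val
    return val


def _apo_side_chain_sasa(apo: StructureModel, tables) -> dict:
    atoms = [(r, a) for r in apo.residues for a in r.heavy_atoms()]
    if not atoms:
        return {}
    coords = np.array([a.position for _, a in atoms])
    radii = np.array([tables.vdw_radius(a.element) for _, a in atoms])
    rep = geometry.sasa(coords, radii)
    out: dict = {}
    for (res, a), area in zip(atoms, rep.per_atom):
        if a.name in set(side_chain_atom_names(res.type)):
            out[res.key] = out.get(res.key, 0.0) + float(area)
    return out


def analyze_pair(apo: StructureModel, holo: StructureModel,
                 ligand: LigandInstance,
                 config: PipelineConfig | None = None,
                 tables: ChemistryTables | None = None) -> PairResult:
    """Full per-residue analysis of one apo/holo pair."""
    config = config or PipelineConfig()
    tables = tables or ChemistryTables.load()
    if config.validate:
        pair = curation.validate_pair(apo, holo, ligand, config.criteria, tables)
        if not pair.accepted:
            return PairResult(pair=pair)
    else:
        pair = _trusting_pair(apo, holo, ligand, tables)

    apo_s, holo_s = pair.apo, pair.holo
    if config.correct_flips:
        apo_s, _ = hbond.correct_flips(apo_s, None, config.hbond, tables)
        holo_s, _ = hbond.correct_flips(holo_s, pair.ligand, config.hbond, tables)
        pair.apo, pair.holo = apo_s, holo_s

    lib = rotamer.load_rotamer_library()
    locked_cys = (rotamer.disulfide_cys_keys(apo_s)
                  | rotamer.disulfide_cys_keys(holo_s))

    calls: dict = {}
    chi_pairs: dict = {}
    rows = []
    analysable = []
    for key in pair.binding_site:
        hres = holo_s.residue(key)
        ares = apo_s.residue(pair.correspondence[key])
        if hres.type in rotamer.EXCLUDED_TYPES or hres.type not in lib:
            continue
        if hres.type == "CYS" and (hres.key in locked_cys or ares.key in locked_cys):
            continue
        apo_chi = rotamer.compute_chis(ares, tables)
        holo_chi = rotamer.compute_chis(hres, tables)
        if not (apo_chi.complete and holo_chi.complete):
            continue
        apo_asn = rotamer.assign_rotamer(apo_chi, lib[hres.type])
        holo_asn = rotamer.assign_rotamer(holo_chi, lib[hres.type])
        ok = rotamer.quality_filter(ares, hres, apo_asn, holo_asn)
        call = rotamer.classify_flexibility(apo_asn, holo_asn, ok)
        calls[key] = call.call
        chi_pairs[key] = (apo_chi, holo_chi)
        analysable.append((key, hres, ares, apo_asn, holo_asn, call,
                           apo_chi, holo_chi))

    result = PairResult(pair=pair)

    per_res_dw: dict = {}
    crit_by_key: dict = {}
    if config.compute_steric:
        site_dw, per_res_dw = steric.delta_wall(pair, tables, config.wall)
        site_crit, crit_records = steric.classify_criticality(
            site_dw, per_res_dw, calls, chi_pairs, config.wall)
        result.site_delta_wall = site_dw
        result.site_critical = site_crit
        crit_by_key = {r.residue_key: r for r in crit_records}

    hb_deltas: dict = {}
    if config.compute_hbonds:
        apo_site = [pair.correspondence[k] for k in pair.binding_site]
        apo_h = hbond.place_polar_hydrogens(apo_s, None, config.hbond, tables)
        holo_h = hbond.place_polar_hydrogens(holo_s, pair.ligand, config.hbond, tables)
        apo_counts = hbond.count_hbonds(apo_h, None, apo_site, config.hbond, tables)
        holo_counts = hbond.count_hbonds(holo_h, pair.ligand, pair.binding_site,
                                         config.hbond, tables)
        for key in pair.binding_site:
            ac = apo_counts[pair.correspondence[key]]
            hc = holo_counts[key]
            ac = hbond.HBondCounts(key, ac.water, ac.protein, ac.ligand)
            hb_deltas[key] = hbond.hbond_delta(ac, hc)

    sas_by_key = _apo_side_chain_sasa(apo_s, tables) if config.compute_sasa else {}

    for key, hres, ares, apo_asn, holo_asn, call, apo_chi, holo_chi in analysable:
        side_b = [a.bfactor for a in ares.side_chain_heavy_atoms()]
        ref = reference_side_chain_sasa(hres.type, tables) if config.compute_sasa else None
        akey = pair.correspondence[key]
        crit = crit_by_key.get(key)
        delta = hb_deltas.get(key)
        rows.append({
            "pair_id": pair.pair_id,
            "residue": hres.label,
            "res_type": hres.type,
            "apo_rotamer": apo_asn.rotamer_id,
            "holo_rotamer": holo_asn.rotamer_id,
            "call": call.call,
            "dchi60": rotamer.delta_chi_flexible(apo_chi, holo_chi),
            "max_dchi": rotamer.max_delta_chi(apo_chi, holo_chi),
            "delta_wall": per_res_dw.get(key, 0.0),
            "critical": bool(crit.critical) if crit else False,
            "minimal_rotation": (crit.minimal_rotation if crit else None),
            "bfactor": float(np.mean(side_b)) if side_b else np.nan,
            "sas_norm": (sas_by_key.get(akey, 0.0) / ref
                         if ref else np.nan),
            "hb_water": delta.water if delta else None,
            "hb_protein": delta.protein if delta else None,
            "hb_ligand": delta.ligand if delta else None,
        })
    result.records = rows
    return result


# ---------------------------------------------------------------------------
# ensemble aggregation

@dataclass
class EnsembleResult:
    records: pd.DataFrame
    site_summary: pd.DataFrame
    histogram_rotamer: stats_report.SiteChangeHistogram
    histogram_dchi: stats_report.SiteChangeHistogram
    scale: dict
    nr_counts: tuple
    minimal_rotation: stats_report.MinimalRotationSummary


def analyze_ensemble(pairs, config: PipelineConfig | None = None,
                     tables: ChemistryTables | None = None) -> EnsembleResult:
    """Run the pipeline over (apo, holo) pairs (the ligand is taken from the
    holo form when not given explicitly) and aggregate the summaries."""
    config = config or PipelineConfig()
    tables = tables or ChemistryTables.load()
    all_rows = []
    site_rows = []
    calls_by_pair: dict = {}
    flags_by_pair: dict = {}
    crit_records = []
    nr_pairs = []
    for item in pairs:
        apo, holo = item[0], item[1]
        ligand = item[2] if len(item) > 2 and isinstance(item[2], LigandInstance) \
            else holo.ligands[0]
        res = analyze_pair(apo, holo, ligand, config, tables)
        pid = res.pair.pair_id
        site_rows.append({
            "pair_id": pid,
            "verdict": res.pair.verdict,
            "reason": res.pair.reason or "",
            "fc": res.pair.fc if res.pair.fc is not None else np.nan,
            "site_delta_wall": (res.site_delta_wall
                                if res.site_delta_wall is not None else np.nan),
            "site_critical": bool(res.site_critical),
            "n_flexible": res.flexible_count(),
            "n_residues": len(res.records),
        })
        if not res.accepted:
            continue
        all_rows.extend(res.records)
        calls_by_pair[pid] = [_Call(r["call"]) for r in res.records]
        flags_by_pair[pid] = [r["dchi60"] for r in res.records]
        for r in res.records:
            crit_records.append(steric.CriticalityRecord(
                (pid, r["residue"]), r["delta_wall"], r["critical"],
                r["call"], r["minimal_rotation"]))
            nr_pairs.append((_Assign(r["apo_rotamer"]), _Assign(r["holo_rotamer"])))

    records = pd.DataFrame(all_rows)
    site_summary = pd.DataFrame(site_rows)
    hist_rot = stats_report.site_change_distribution(calls_by_pair, "rotamer")
    hist_dchi = stats_report.site_change_distribution(flags_by_pair, "delta_chi_60")
    scale = rotamer.probability_scale(
        [rotamer.FlexibilityCall(None, r["res_type"], r["apo_rotamer"],
                                 r["holo_rotamer"], r["call"])
         for r in all_rows])
    nr_counts = stats_report.nr_count_comparison(nr_pairs)
    minrot = stats_report.minimal_rotation_summary(crit_records)
    return EnsembleResult(records, site_summary, hist_rot, hist_dchi,
                          scale, nr_counts, minrot)


class _Call:
    __slots__ = ("call",)

    def __init__(self, call):
        self.call = call


class _Assign:
    __slots__ = ("rotamer_id",)

    def __init__(self, rid):
        self.rotamer_id = rid

    @property
    def is_nr(self):
        return self.rotamer_id == rotamer.NR


def write_report(result: EnsembleResult, out_dir) -> list:
    """Deterministic TSV report bundle (byte-identical across runs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _dump(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6f",
                  lineterminator="\n")
        paths.append(p)

    if not result.records.empty:
        _dump(result.records.sort_values(["pair_id", "residue"])
              .reset_index(drop=True), "residue_records.tsv")
    else:
        _dump(result.records, "residue_records.tsv")
    _dump(result.site_summary.sort_values("pair_id").reset_index(drop=True),
          "site_summary.tsv")
    hist_rows = [{"method": h.method, "n_changes": k, "n_sites": v,
                  "cumulative": h.cumulative[k]}
                 for h in (result.histogram_rotamer, result.histogram_dchi)
                 for k, v in sorted(h.counts.items())]
    _dump(pd.DataFrame(hist_rows), "site_change_histogram.tsv")
    scale_rows = [{"res_type": t, "n_changed": e.n_changed, "n_total": e.n_total,
                   "p": e.p, "error": e.error}
                  for t, e in sorted(result.scale.items())]
    _dump(pd.DataFrame(scale_rows), "flexibility_scale.tsv")
    mr = result.minimal_rotation
    _dump(pd.DataFrame([{"n_critical": mr.n_critical, "n_minimal": mr.n_minimal,
                         "fraction": mr.fraction if mr.fraction is not None else np.nan,
                         "apo_nr": result.nr_counts[0],
                         "holo_nr": result.nr_counts[1]}]),
          "minimal_rotation.tsv")
    return paths
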