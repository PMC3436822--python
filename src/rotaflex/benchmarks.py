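"""Self-validation procedures over ground-truthed synthetic data.

Each function here regenerates its inputs from a seed, runs the relevant
pipeline stage and returns the measured quantities.  The test suite asserts
on these numbers and the reproduction script reports them, so both always
run the same code path.  Problem sizes (200 rotamer draws, 100 Eq-recovery
replicates, 200-pair ensembles, 50 clash fixtures, 20 hydrogen-bond
pockets) are the package's standard validation sizes.
"""
from __future__ import annotations

import numpy as np

from . import hbond, rotamer, steric
from .curation import validate_pair
from .geometry import sasa, sphere_points
from .pipeline import PipelineConfig, analyze_ensemble, analyze_pair
from .rotamer import assign_rotamer, compute_chis, load_rotamer_library
from .stats_report import minimal_rotation_summary, site_change_distribution
from .steric import CriticalityRecord, WallParameters, delta_wall
from .structio import ChemistryTables
from .synthetic import (HBondPlant, SyntheticPlan, build_residue,
                        generate_ensemble, generate_pair)

LIGHT_CONFIG = PipelineConfig(validate=False, compute_sasa=False,
                              compute_hbonds=False, compute_steric=False)


# ---------------------------------------------------------------------------
# rotamer assignment round trip

def rotamer_roundtrip(n: int = 200, sigma: float = 5.0, offset: float = 45.0,
                      seed: int = 0) -> dict:
    """Build residues at library means + wrapped-normal noise and re-assign.

    Returns the fraction recovered exactly, and the fraction classified NR
    after shifting the same draws by ``offset`` degrees on every chi.
    """
    rng = np.random.default_rng(seed)
    lib = load_rotamer_library()
    tables = ChemistryTables.load()
    types = sorted(t for t in lib if t not in ("PRO", "ALA", "GLY"))
    n_correct = n_nr = 0
    for _ in range(n):
        t = types[rng.integers(len(types))]
        rot = lib[t][rng.integers(len(lib[t]))]
        noisy = [m + rng.normal(0.0, sigma) for m in rot.means]
        asn = assign_rotamer(compute_chis(build_residue(t, noisy), tables), lib[t])
        n_correct += asn.rotamer_id == rot.rotamer_id
        shifted = [v + offset for v in noisy]
        asn2 = assign_rotamer(compute_chis(build_residue(t, shifted), tables),
                              lib[t])
        n_nr += asn2.is_nr
    return {"n": n, "accuracy": n_correct / n, "nr_fraction": n_nr / n}


# ---------------------------------------------------------------------------
# probability-of-change estimator recovery

def probability_recovery(n_reps: int = 100, n_obs: int = 500, p: float = 0.3,
                         seed: int = 0) -> dict:
    """Simulate Bernoulli flexibility outcomes and check the estimate lands
    within twice its own reported error of the truth."""
    rng = np.random.default_rng(seed)
    n_within = 0
    for _ in range(n_reps):
        k = int(rng.binomial(n_obs, p))
        est = rotamer.flexibility_probability(k, n_obs)
        if abs(est.p - p) <= 2.0 * est.error:
            n_within += 1
    return {"n_reps": n_reps, "n_within": n_within,
            "coverage": n_within / n_reps}


# ---------------------------------------------------------------------------
# per-site change-count distribution recovery

def _poisson_envelopes(n_pairs: int, lam: float, max_k: int,
                       n_sim: int = 2000, seed: int = 1234) -> dict:
    """Monte-Carlo 95% envelopes of per-bin counts for a multinomial sample
    of site change-counts drawn from a (truncated) Poisson."""
    rng = np.random.default_rng(seed)
    draws = np.minimum(rng.poisson(lam, size=(n_sim, n_pairs)), max_k)
    env = {}
    for k in range(max_k + 1):
        counts = (draws == k).sum(axis=1)
        env[k] = (float(np.percentile(counts, 2.5)),
                  float(np.percentile(counts, 97.5)))
    return env


def distribution_recovery(n_pairs: int = 200, lam: float = 1.5,
                          seed: int = 0) -> dict:
    """Generate an ensemble with Poisson-planted flexible counts, run the
    rotamer pipeline, and compare the recovered per-site histogram with the
    plants and with Monte-Carlo multinomial envelopes."""
    ens = generate_ensemble(n_pairs, ("poisson", lam), seed=seed)
    result = analyze_ensemble([(a, h) for a, h, _ in ens], LIGHT_CONFIG)
    hist = result.histogram_rotamer
    planted = {}
    for _, _, t in ens:
        planted[t.expected_flexible_count] = \
            planted.get(t.expected_flexible_count, 0) + 1
    max_k = max(planted)
    env = _poisson_envelopes(n_pairs, lam, max_k=max(max_k, 8))
    inside = all(env[k][0] <= hist.counts.get(k, 0) <= env[k][1]
                 for k in range(max(max_k, 8) + 1))
    return {
        "n_pairs": n_pairs,
        "recovered_equals_planted": hist.counts == dict(sorted(planted.items())),
        "inside_envelopes": inside,
        "cumulative_at_max": hist.cumulative[max(hist.counts)],
        "fraction_sites_changed": 1.0 - hist.counts.get(0, 0) / n_pairs,
        "cumulative_at_5": hist.cumulative.get(5, 1.0) if max(hist.counts) >= 5
        else 1.0,
    }


# ---------------------------------------------------------------------------
# WALL potential checks

def _naive_wall(prot, lig, tables, params):
    total = 0.0
    for a in prot:
        ra = tables.vdw_radius(a.element)
        for b in lig:
            rb = tables.vdw_radius(b.element)
            d = float(np.linalg.norm(a.position - b.position))
            rsum = ra + rb
            if d < rsum:
                total += params.k_wall * ((rsum - d) / rsum) ** 4
    return total


def wall_oracle_agreement(n_configs: int = 100, seed: int = 0) -> dict:
    """Vectorised WALL vs an independent double loop on random clusters."""
    rng = np.random.default_rng(seed)
    tables = ChemistryTables.load()
    params = WallParameters()
    max_rel = 0.0
    n_zero_consistent = 0
    n_done = 0
    while n_done < n_configs:
        res = build_residue("LYS", [-67, 180, 180, 180])
        shift = rng.normal(scale=2.0, size=3)
        lig = [type(res.atoms[0])(f"C{k}", "C",
                                  rng.normal(scale=3.0, size=3) + shift)
               for k in range(6)]
        try:
            score = steric.wall_potential([res], lig, tables, params)
        except ValueError:
            continue
        n_done += 1
        oracle = _naive_wall(res.heavy_atoms(), lig, tables, params)
        if oracle > 0:
            max_rel = max(max_rel, abs(score.total - oracle) / oracle)
            n_zero_consistent += score.total > 0
        else:
            n_zero_consistent += score.total == 0
    return {"n_configs": n_configs, "max_rel_diff": max_rel,
            "zero_iff_no_overlap": n_zero_consistent == n_configs}


_CLASH_INDICES = (0, 1, 2, 3, 4, 5, 8, 9, 10)   # pocket slots usable for clashes


def planted_clash_recovery(n_fixtures: int = 50, depth: float = 0.5,
                           seed: int = 0) -> dict:
    """Criticality classification on pockets with one planted 0.5 A overlap."""
    params = WallParameters()
    n_ok = 0
    for f in range(n_fixtures):
        i = _CLASH_INDICES[f % len(_CLASH_INDICES)]
        j = _CLASH_INDICES[(f // len(_CLASH_INDICES) + f + 1) % len(_CLASH_INDICES)]
        flex = (i,) if i == j else tuple(sorted({i, j}))
        plan = SyntheticPlan(flexible=flex, clash_residue=i, clash_depth=depth,
                             seed=seed + f)
        apo, holo, truth = generate_pair(plan)
        pair = validate_pair(apo, holo, holo.ligands[0])
        if not pair.accepted:
            continue
        site_delta, per_res = delta_wall(pair)
        site_crit = site_delta > params.site_threshold
        crit = {k for k, v in per_res.items() if v > params.residue_threshold}
        if site_crit and truth.clash_residue in crit:
            n_ok += 1
    return {"n_fixtures": n_fixtures, "n_recovered": n_ok}


def identical_forms_delta(seed: int = 0) -> float:
    apo, holo, _ = generate_pair(SyntheticPlan(seed=seed))
    pair = validate_pair(apo, holo, holo.ligands[0])
    site_delta, _ = delta_wall(pair)
    return float(site_delta)


# ---------------------------------------------------------------------------
# minimal-rotation accounting

def minimal_rotation_accounting(n_small: int = 37, n_large: int = 133,
                                small_deg: float = 10.0,
                                large_deg: float = 40.0) -> dict:
    """Partition planted critical residues by the <15 degree criterion.

    Mirrors the bookkeeping over sterically critical residues: each record
    carries real chi vectors and goes through the minimal-rotation test.
    """
    records = []
    k = 0
    for n_records, delta, call in ((n_small, small_deg, "rigid"),
                                   (n_large, large_deg, "flexible")):
        for _ in range(n_records):
            k += 1
            apo_chi = rotamer.ChiVector(("A", k, ""), "SER", [0.0], True)
            holo_chi = rotamer.ChiVector(("A", k, ""), "SER", [delta], True)
            records.append(CriticalityRecord(
                ("A", k, ""), 100.0, True, call,
                steric.minimal_rotation_test(apo_chi, holo_chi)))
    summary = minimal_rotation_summary(records)
    return {"n_critical": summary.n_critical, "n_minimal": summary.n_minimal,
            "fraction": summary.fraction}


# ---------------------------------------------------------------------------
# hydrogen-bond exactness

_HB_ROSTER = ("GLN", "LEU", "ASN", "VAL", "ASP", "LYS")
_HB_GEOMETRIES = ((1.4, 180.0, False), (1.5, 180.0, True), (2.7, 180.0, True),
                  (2.8, 180.0, False), (2.0, 85.0, False), (2.0, 90.0, True))


def hbond_pocket_exactness(n_pockets: int = 20, seed: int = 0) -> dict:
    """Detection and delta calls on pockets with boundary-spanning plants.

    Each pocket plants three donor-side geometries (cycling through both
    sides of every distance/angle boundary) plus one water with a chosen
    fate.  Bond counts must equal the planted counts exactly and every
    conserved/gain/loss call must match.
    """
    tables = ChemistryTables.load()
    n_sets_ok = n_calls_ok = 0
    for s in range(n_pockets):
        plants = []
        for j, di in enumerate((0, 2, 5)):
            d, th, det = _HB_GEOMETRIES[(s + 2 * j) % len(_HB_GEOMETRIES)]
            plants.append(HBondPlant(di, "ligand", d_ha=d, theta=th,
                                     detectable=det))
        plants.append(HBondPlant(4, "water",
                                 presence=("both", "apo", "holo")[s % 3]))
        plan = SyntheticPlan(n_residues=6, roster=_HB_ROSTER,
                             hbond_plants=tuple(plants), seed=seed + s)
        apo, holo, truth = generate_pair(plan)
        lig = holo.ligands[0]
        holo_h = hbond.place_polar_hydrogens(holo, lig, tables=tables)
        apo_h = hbond.place_polar_hydrogens(apo, None, tables=tables)
        holo_counts = hbond.count_hbonds(holo_h, lig, tables=tables)
        apo_counts = hbond.count_hbonds(apo_h, None, tables=tables)

        sets_ok = calls_ok = True
        for res in holo.residues:
            key = res.key
            pb = truth.planted_bonds.get(key, {"ligand": 0, "water": 0})
            delta = truth.expected_hbond_delta.get(
                key, {"water": "conserved", "protein": "conserved",
                      "ligand": "conserved"})
            exp_holo_w = pb["water"] if delta["water"] != "loss" else 0
            exp_apo_w = pb["water"] if delta["water"] != "gain" else 0
            got = (holo_counts[key].ligand, holo_counts[key].water,
                   holo_counts[key].protein, apo_counts[key].water,
                   apo_counts[key].protein)
            if got != (pb["ligand"], exp_holo_w, 0, exp_apo_w, 0):
                sets_ok = False
            ac = hbond.HBondCounts(key, apo_counts[key].water,
                                   apo_counts[key].protein, 0)
            call = hbond.hbond_delta(ac, holo_counts[key])
            if (call.water, call.protein, call.ligand) != \
                    (delta["water"], delta["protein"], delta["ligand"]):
                calls_ok = False
        n_sets_ok += sets_ok
        n_calls_ok += calls_ok
    return {"n_pockets": n_pockets, "n_exact_sets": n_sets_ok,
            "n_delta_match": n_calls_ok}


# ---------------------------------------------------------------------------
# SASA oracle

def sasa_oracle_agreement(seed: int = 0, oracle_points: int = 10 ** 6) -> dict:
    """Closed-form isolated sphere plus two-sphere numerical comparisons."""
    sphere = sasa(np.zeros((1, 3)), [1.7], probe=1.4)
    closed = 4.0 * np.pi * 3.1 ** 2
    sphere_rel = abs(sphere.total - closed) / closed

    rng = np.random.default_rng(seed)
    max_rel = 0.0
    for separation in (1.0, 2.2, 3.4, 4.6):
        coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
        radii = np.array([1.7, 1.52])
        ours = sasa(coords, radii, probe=1.4).per_atom
        for i in range(2):
            ri = radii[i] + 1.4
            pts = rng.normal(size=(oracle_points, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts = coords[i] + ri * pts
            j = 1 - i
            free = ((pts - coords[j]) ** 2).sum(axis=1) >= (radii[j] + 1.4) ** 2
            oracle = 4.0 * np.pi * ri * ri * free.mean()
            if oracle > 0:
                max_rel = max(max_rel, abs(ours[i] - oracle) / oracle)
    return {"sphere_rel_err": float(sphere_rel),
            "two_sphere_max_rel_err": float(max_rel)}


# ---------------------------------------------------------------------------
# curation gates

GATES = ("resolution", "identity", "overlap", "buffer", "ligand_size",
         "covalent", "site_size", "multi_chain", "burial", "missing_atoms",
         "extra_ligand", "site_rmsd")


def curation_gate_checks(seed: int = 0) -> dict:
    """One negative control per curation gate plus the clean fixture."""
    n_ok = 0
    details = {}
    for gate in GATES:
        apo, holo, _ = generate_pair(SyntheticPlan(seed=seed, violate=gate))
        pair = validate_pair(apo, holo, holo.ligands[0])
        good = (not pair.accepted) and pair.reason == gate
        details[gate] = pair.reason
        n_ok += good
    apo, holo, _ = generate_pair(SyntheticPlan(seed=seed))
    clean = validate_pair(apo, holo, holo.ligands[0])
    n_ok += clean.accepted
    details["clean"] = clean.verdict
    return {"n_checks": len(GATES) + 1, "n_correct": n_ok, "details": details}


# ---------------------------------------------------------------------------
# end-to-end determinism

def determinism_check(out_dir, n_pairs: int = 12, seed: int = 0) -> bool:
    """Full pipeline twice on the same ensemble: report bytes must match."""
    from pathlib import Path

    from .pipeline import write_report

    out_dir = Path(out_dir)
    ens = generate_ensemble(n_pairs, ("poisson", 1.5), seed=seed)
    pairs = [(a, h) for a, h, _ in ens]
    files = []
    for run in ("run1", "run2"):
        result = analyze_ensemble(pairs)
        files.append(write_report(result, out_dir / run))
    return all(f1.read_bytes() == f2.read_bytes()
               for f1, f2 in zip(files[0], files[1]))
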