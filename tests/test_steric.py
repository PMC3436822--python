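import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rotaflex.curation import validate_pair
from rotaflex.rotamer import ChiVector
from rotaflex.steric import (WallParameters, build_apo_bound,
                             classify_criticality, delta_wall,
                             minimal_rotation_test, wall_potential)
from rotaflex.structio import Atom, LigandInstance
from rotaflex.synthetic import SyntheticPlan, build_residue, generate_pair


def _naive_wall(prot_atoms, lig_atoms, tables, params):
    """Independent double-loop WALL evaluation."""
    total = 0.0
    for res_key, a in prot_atoms:
        ra = tables.vdw_radius(a.element)
        for b in lig_atoms:
            rb = tables.vdw_radius(b.element)
            d = float(np.linalg.norm(a.position - b.position))
            rsum = ra + rb
            if d < rsum:
                total += params.k_wall * ((rsum - d) / rsum) ** 4
    return total


def _carbon(name, pos):
    return Atom(name, "C", np.asarray(pos, float))


class TestWallPotential:
    def test_zero_when_no_overlap(self, tables):
        res = build_residue("VAL", [175.0])
        lig = [_carbon("C1", [30.0, 0, 0])]
        score = wall_potential([res], lig, tables)
        assert score.total == 0.0
        assert score.per_residue == {}

    def test_boundary_contact_contributes_zero(self, tables):
        res = build_residue("GLY", [])
        res.atoms = [_carbon("CA", [0.0, 0.0, 0.0])]
        # exactly r_i + r_j apart: zero overlap, zero penalty
        score = wall_potential([res], [_carbon("C1", [3.4, 0.0, 0.0])], tables)
        assert score.total == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_hand_value(self, tables):
        # C...C at 3.0 with radii 1.7+1.7: K*(0.4/3.4)^4
        res = build_residue("GLY", [])
        far = [a for a in res.atoms]
        for a in far:
            a.position = a.position + np.array([0.0, 0.0, 40.0])
        res.atoms = [_carbon("CA", [0.0, 0.0, 0.0])]
        lig = [_carbon("C1", [3.0, 0.0, 0.0])]
        score = wall_potential([res], lig, tables)
        assert score.total == pytest.approx(1e6 * (0.4 / 3.4) ** 4, rel=1e-12)

    def test_matches_naive_double_loop_on_random_configs(self, tables, rng):
        params = WallParameters()
        for _ in range(100):
            res = build_residue("LYS", [-67, 180, 180, 180])
            shift = rng.normal(scale=2.0, size=3)
            lig = [_carbon(f"C{k}", rng.normal(scale=3.0, size=3) + shift)
                   for k in range(6)]
            try:
                score = wall_potential([res], lig, tables, params)
            except ValueError:
                continue  # coincident atoms in a random draw
            oracle = _naive_wall([(res.key, a) for a in res.heavy_atoms()],
                                 lig, tables, params)
            assert score.total == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_monotone_as_clash_deepens(self, tables):
        res = build_residue("GLY", [])
        res.atoms = [_carbon("CA", [0.0, 0.0, 0.0])]
        vals = [wall_potential([res], [_carbon("C1", [d, 0, 0])], tables).total
                for d in (3.3, 3.0, 2.7, 2.4)]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))

    def test_invariant_under_rigid_motion(self, tables):
        res = build_residue("LEU", [-65, 175])
        lig = [_carbon("C1", [2.0, 1.0, 0.5]), _carbon("C2", [3.0, -1.0, 0.0])]
        base = wall_potential([res], lig, tables).total
        rot = Rotation.from_euler("zyx", [12, 34, 56], degrees=True).as_matrix()
        tr = np.array([4.0, 5.0, 6.0])
        res2 = res.copy()
        for a in res2.atoms:
            a.position = rot @ a.position + tr
        lig2 = [_carbon(a.name, rot @ a.position + tr) for a in lig]
        assert wall_potential([res2], lig2, tables).total == \
            pytest.approx(base, rel=1e-9)

    def test_coincident_atoms_raise(self, tables):
        res = build_residue("GLY", [])
        res.atoms = [_carbon("CA", [0.0, 0.0, 0.0])]
        with pytest.raises(ValueError):
            wall_potential([res], [_carbon("C1", [0.0, 0.0, 0.0])], tables)

    def test_total_equals_sum_of_residue_contributions(self, tables):
        apo, holo, _ = generate_pair(SyntheticPlan(seed=5))
        score = wall_potential(holo.residues, holo.ligands[0].atoms, tables)
        assert score.total == pytest.approx(sum(score.per_residue.values()),
                                            abs=1e-9)

    def test_pluggable_forms(self, tables):
        res = build_residue("GLY", [])
        res.atoms = [_carbon("CA", [0.0, 0.0, 0.0])]
        lig = [_carbon("C1", [3.0, 0.0, 0.0])]
        quartic = wall_potential([res], lig, tables, WallParameters()).total
        quadratic = wall_potential([res], lig, tables,
                                   WallParameters(form="quadratic")).total
        step = wall_potential([res], lig, tables, WallParameters(form="step")).total
        assert quadratic == pytest.approx(1e6 * (0.4 / 3.4) ** 2, rel=1e-12)
        assert step == pytest.approx(1e6)
        assert quartic < quadratic < step


class TestApoBound:
    def test_identical_forms_transplant_in_place(self):
        apo, holo, _ = generate_pair(SyntheticPlan(seed=6))
        pair = validate_pair(apo, holo, holo.ligands[0])
        apo_bound, transform = build_apo_bound(pair)
        d = np.abs(apo_bound.ligands[-1].coords() - pair.ligand.coords())
        assert d.max() < 1e-9

    def test_rigidly_moved_apo_reproduces_pocket_geometry(self):
        apo, holo, _ = generate_pair(SyntheticPlan(seed=6))
        rot = Rotation.from_euler("xyz", [15, -25, 35], degrees=True).as_matrix()
        shift = np.array([10.0, -5.0, 2.0])
        for res in apo.residues:
            for a in res.atoms:
                a.position = rot @ a.position + shift
        pair = validate_pair(apo, holo, holo.ligands[0])
        assert pair.accepted
        apo_bound, _ = build_apo_bound(pair)
        lig = apo_bound.ligands[-1].coords()
        # pairwise ligand-site distances must match the holo pocket
        for hres, key in zip(holo.residues, [r.key for r in apo_bound.residues]):
            ares = apo_bound.residue(key)
            for name in ("CA", "CB"):
                dh = np.linalg.norm(pair.ligand.coords() -
                                    hres.atom(name).position, axis=1)
                da = np.linalg.norm(lig - ares.atom(name).position, axis=1)
                assert np.allclose(np.sort(dh), np.sort(da), atol=1e-6)

    def test_delta_wall_zero_for_identical_forms(self):
        apo, holo, _ = generate_pair(SyntheticPlan(seed=6))
        pair = validate_pair(apo, holo, holo.ligands[0])
        site_delta, per_res = delta_wall(pair)
        assert site_delta == pytest.approx(0.0, abs=1e-9)
        assert all(abs(v) < 1e-9 for v in per_res.values())

    def test_planted_clash_concentrates_on_planted_residue(self, tables):
        plan = SyntheticPlan(flexible=(1,), clash_residue=1, clash_depth=0.5,
                             seed=7)
        apo, holo, truth = generate_pair(plan)
        pair = validate_pair(apo, holo, holo.ligands[0])
        site_delta, per_res = delta_wall(pair)
        params = WallParameters()
        assert site_delta > params.site_threshold
        critical = {k for k, v in per_res.items() if v > params.residue_threshold}
        assert critical == {truth.clash_residue}


class TestCriticality:
    def test_thresholds(self):
        site_crit, records = classify_criticality(
            10.0, {("A", 1, ""): 30.0, ("A", 2, ""): 10.0})
        assert not site_crit
        flags = {r.residue_key: r.critical for r in records}
        assert flags == {("A", 1, ""): True, ("A", 2, ""): False}

    def test_minimal_rotation_annotation_only_for_critical(self):
        chi = {("A", 1, ""): (ChiVector(("A", 1, ""), "SER", [0.0], True),
                              ChiVector(("A", 1, ""), "SER", [10.0], True)),
               ("A", 2, ""): (ChiVector(("A", 2, ""), "SER", [0.0], True),
                              ChiVector(("A", 2, ""), "SER", [40.0], True))}
        _, records = classify_criticality(
            200.0, {("A", 1, ""): 30.0, ("A", 2, ""): 5.0},
            flexibility_calls={("A", 1, ""): "rigid", ("A", 2, ""): "flexible"},
            chi_pairs=chi)
        by_key = {r.residue_key: r for r in records}
        assert by_key[("A", 1, "")].minimal_rotation is True
        assert by_key[("A", 2, "")].minimal_rotation is None


class TestMinimalRotation:
    def _vec(self, vals):
        return ChiVector(("A", 1, ""), "LEU", list(vals), True)

    def test_small_changes_pass(self):
        assert minimal_rotation_test(self._vec([0, 0]), self._vec([3, 7]))

    def test_15_exactly_fails_strictly(self):
        assert not minimal_rotation_test(self._vec([0]),
                                         ChiVector(("A", 1, ""), "SER", [15.0], True))

    def test_just_under_15_passes(self):
        assert minimal_rotation_test(ChiVector(("A", 1, ""), "SER", [0.0], True),
                                     ChiVector(("A", 1, ""), "SER", [14.9], True))
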