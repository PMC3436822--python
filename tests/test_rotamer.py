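import math

import numpy as np
import pytest

from rotaflex import rotamer
from rotaflex.rotamer import (ChiVector, IncompleteChiError, NR,
                              assign_rotamer, classify_flexibility,
                              compute_chis, delta_chi_flexible,
                              disulfide_cys_keys, flexibility_probability,
                              max_delta_chi, normalize_chi, quality_filter)
from rotaflex.structio import Atom, StructureModel
from rotaflex.synthetic import build_residue


class TestComputeChis:
    def test_ser_built_at_target_chi(self, tables):
        res = build_residue("SER", [62.0])
        chis = compute_chis(res, tables)
        assert chis.complete
        assert chis.values[0] == pytest.approx(62.0, abs=0.5)

    @pytest.mark.parametrize("res_type,n", [("VAL", 1), ("SER", 1), ("LEU", 2),
                                            ("MET", 3), ("LYS", 4), ("ARG", 4)])
    def test_chi_vector_lengths(self, res_type, n, tables, library):
        targets = list(library[res_type][0].means)
        chis = compute_chis(build_residue(res_type, targets), tables)
        assert len(chis) == n

    def test_symmetric_chi2_normalised_to_half_circle(self, tables):
        # a Phe ring built at chi2 = 150 reads as -30 under 180-deg symmetry
        res = build_residue("PHE", [-65.0, 150.0])
        chis = compute_chis(res, tables)
        assert chis.values[1] == pytest.approx(-30.0, abs=0.5)
        assert normalize_chi("PHE", 2, 150.0) == pytest.approx(-30.0)

    def test_missing_atom_invalidates_deeper_chis(self, tables):
        res = build_residue("LYS", [-67, 180, 180, 180])
        res.atoms = [a for a in res.atoms if a.name != "CD"]
        chis = compute_chis(res, tables)
        assert not chis.complete
        assert not math.isnan(chis.values[0])       # chi1 N-CA-CB-CG intact
        assert all(math.isnan(v) for v in chis.values[1:])


class TestAssignRotamer:
    def test_library_self_consistency_every_entry(self, library, tables):
        # building a residue at each rotamer's own means must recover it
        for res_type, rots in library.items():
            for rot in rots:
                res = build_residue(res_type, rot.means)
                asn = assign_rotamer(compute_chis(res, tables), rots)
                assert asn.rotamer_id == rot.rotamer_id, (res_type, rot.rotamer_id)

    def test_exact_mean_gives_zero_deviation(self, library):
        chis = ChiVector(("A", 1, ""), "SER", [62.0], True)
        asn = assign_rotamer(chis, library["SER"])
        assert asn.rotamer_id == "p"
        assert asn.deviations[0] == pytest.approx(0.0)

    def test_31_degrees_beyond_every_mean_is_nr(self, library):
        chis = ChiVector(("A", 1, ""), "SER", [62.0 + 31.0], True)
        # 93 is 31 from p, 90 from t(-177 -> 270), 158 from m
        asn = assign_rotamer(chis, library["SER"])
        assert asn.is_nr

    def test_boundary_30_degrees_is_inclusive(self, library):
        chis = ChiVector(("A", 1, ""), "SER", [62.0 + 30.0], True)
        asn = assign_rotamer(chis, library["SER"])
        assert asn.rotamer_id == "p"

    def test_incomplete_vector_raises(self, library):
        chis = ChiVector(("A", 1, ""), "SER", [math.nan], False)
        with pytest.raises(IncompleteChiError):
            assign_rotamer(chis, library["SER"])

    def test_deterministic(self, library, rng):
        for _ in range(20):
            v = float(rng.uniform(-180, 180))
            a1 = assign_rotamer(ChiVector(("A", 1, ""), "THR", [v], True),
                                library["THR"])
            a2 = assign_rotamer(ChiVector(("A", 1, ""), "THR", [v], True),
                                library["THR"])
            assert a1.rotamer_id == a2.rotamer_id


class TestRoundTripRecovery:
    """Noisy planted rotamers must be recovered; 45-degree offsets never."""

    def test_noise_sigma5_recovers_100_percent(self, library, tables, rng):
        n_ok = n = 0
        types = sorted(t for t in library if t not in ("PRO", "ALA", "GLY"))
        for _ in range(200):
            t = types[rng.integers(len(types))]
            rot = library[t][rng.integers(len(library[t]))]
            noisy = [m + rng.normal(0, 5) for m in rot.means]
            res = build_residue(t, noisy)
            asn = assign_rotamer(compute_chis(res, tables), library[t])
            n += 1
            n_ok += asn.rotamer_id == rot.rotamer_id
        assert n_ok == n

    def test_offset_45_never_recovers(self, library, tables, rng):
        types = sorted(t for t in library if t not in ("PRO", "ALA", "GLY"))
        for _ in range(200):
            t = types[rng.integers(len(types))]
            rot = library[t][rng.integers(len(library[t]))]
            res = build_residue(t, [m + 45.0 for m in rot.means])
            asn = assign_rotamer(compute_chis(res, tables), library[t])
            assert asn.rotamer_id != rot.rotamer_id


class TestQualityFilter:
    def _nr(self):
        return rotamer.RotamerAssignment(("A", 1, ""), "SER", NR)

    def _rot(self):
        return rotamer.RotamerAssignment(("A", 1, ""), "SER", "p", (0.0,))

    def _ser(self, bfactor=15.0, occupancy=1.0, altloc=""):
        res = build_residue("SER", [62.0])
        for a in res.atoms:
            if a.name == "OG":
                a.bfactor = bfactor
                a.occupancy = occupancy
                a.altloc = altloc
        return res

    def test_nr_with_high_bfactor_excluded(self):
        assert not quality_filter(self._ser(bfactor=45.0), self._ser(),
                                  self._nr(), self._rot())

    def test_nr_with_clean_side_chain_retained(self):
        assert quality_filter(self._ser(bfactor=35.0), self._ser(),
                              self._nr(), self._rot())

    def test_rotameric_side_chain_unaffected_by_bad_density(self):
        # the filter only targets NR conformations
        assert quality_filter(self._ser(bfactor=80.0), self._ser(bfactor=80.0),
                              self._rot(), self._rot())

    @pytest.mark.parametrize("kw", [dict(occupancy=0.9), dict(altloc="A")])
    def test_partial_occupancy_or_altloc_excludes_nr(self, kw):
        assert not quality_filter(self._ser(**kw), self._ser(),
                                  self._nr(), self._rot())


class TestClassifyFlexibility:
    def _a(self, rid):
        return rotamer.RotamerAssignment(("A", 1, ""), "LEU", rid)

    def test_same_rotamer_is_rigid(self):
        assert classify_flexibility(self._a("mt"), self._a("mt")).call == "rigid"

    def test_different_rotamers_are_flexible(self):
        assert classify_flexibility(self._a("t"), self._a("mt")).call == "flexible"

    def test_single_nr_is_flexible(self):
        assert classify_flexibility(self._a(NR), self._a("mt")).call == "flexible"

    def test_double_nr_is_excluded(self):
        assert classify_flexibility(self._a(NR), self._a(NR)).call == "excluded_NR_NR"

    def test_quality_failure_overrides(self):
        call = classify_flexibility(self._a("mt"), self._a("tp"), quality_ok=False)
        assert call.call == "excluded_quality"


class TestProbability:
    @pytest.mark.parametrize("n_r,n_t,p,err", [
        (0, 50, 0.0, 0.0),
        (10, 40, 0.25, 0.06847),
        (40, 40, 1.0, 0.0),
    ])
    def test_estimate_and_binomial_error(self, n_r, n_t, p, err):
        est = flexibility_probability(n_r, n_t)
        assert est.p == pytest.approx(p)
        assert est.error == pytest.approx(err, abs=1e-4)

    def test_binomial_error_matches_bootstrap(self, rng):
        # closed form vs resampling for (10, 40)
        obs = np.array([1] * 10 + [0] * 30)
        boots = rng.choice(obs, size=(10 ** 5, 40), replace=True).mean(axis=1)
        est = flexibility_probability(10, 40)
        assert est.error == pytest.approx(float(boots.std()), rel=0.02)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            flexibility_probability(1, 0)
        with pytest.raises(ValueError):
            flexibility_probability(5, 4)

    def test_scale_excludes_gly_ala_pro(self):
        calls = [rotamer.FlexibilityCall(("A", i, ""), t, "a", "b", "flexible")
                 for i, t in enumerate(["PRO", "SER", "LEU"])]
        scale = rotamer.probability_scale(calls)
        assert "PRO" not in scale
        assert set(scale) == {"SER", "LEU"}


class TestDeltaChi:
    def _vec(self, t, vals):
        return ChiVector(("A", 1, ""), t, list(vals), True)

    def test_threshold_inclusive(self):
        assert delta_chi_flexible(self._vec("LEU", [0, 0]),
                                  self._vec("LEU", [5, 60]))
        assert not delta_chi_flexible(self._vec("SER", [0]),
                                      self._vec("SER", [59]))

    def test_circular_wrap(self):
        # -170 vs 170 differ by 20 degrees on the circle
        assert not delta_chi_flexible(self._vec("SER", [-170]),
                                      self._vec("SER", [170]))
        assert max_delta_chi(self._vec("SER", [-170]),
                             self._vec("SER", [170])) == pytest.approx(20.0)

    def test_symmetric_terminal_chi_uses_180_period(self):
        # Phe chi2: 150 and -30 name the same ring orientation
        assert not delta_chi_flexible(self._vec("PHE", [-65, -30]),
                                      self._vec("PHE", [-65, -30.0]))
        assert max_delta_chi(self._vec("PHE", [-65, 150 - 180]),
                             self._vec("PHE", [-65, -30])) == pytest.approx(0.0)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            delta_chi_flexible(self._vec("SER", [0]), self._vec("LEU", [0, 0]))


def test_two_sigma_interval_exact_coverage():
    """The reported binomial error is correctly calibrated: the exact
    probability (binomial pmf, no simulation) that the estimate falls within
    twice its own reported error of the truth is at least the nominal 95%."""
    from scipy import stats as sps
    n, p = 500, 0.3
    ks = np.arange(n + 1)
    est = np.array([flexibility_probability(int(k), n).p for k in ks])
    err = np.array([flexibility_probability(int(k), n).error for k in ks])
    inside = np.abs(est - p) <= 2.0 * err
    coverage = float(sps.binom.pmf(ks, n, p)[inside].sum())
    assert coverage >= 0.95


def test_disulfide_detection():
    c1 = build_residue("CYS", [-65], seq_num=1)
    c2 = build_residue("CYS", [-65], seq_num=2)
    sg1 = c1.atom("SG").position
    for a in c2.atoms:
        a.position = a.position + (sg1 + np.array([2.0, 0, 0]) - c2.atom("SG").position)
    st = StructureModel(residues=[c1, c2])
    assert disulfide_cys_keys(st) == {c1.key, c2.key}
    # move them apart: no disulfide
    for a in c2.atoms:
        a.position = a.position + np.array([10.0, 0, 0])
    assert disulfide_cys_keys(st) == set()
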