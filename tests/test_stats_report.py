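import numpy as np
import pandas as pd
import pytest

from rotaflex.rotamer import ProbabilityEstimate
from rotaflex.stats_report import (GroupComparison, compare_flexible_vs_rigid,
                                   entropy_correlation,
                                   hbond_delta_fractions,
                                   minimal_rotation_summary,
                                   nr_count_comparison,
                                   site_change_distribution)
from rotaflex.steric import CriticalityRecord


class _Call:
    def __init__(self, call):
        self.call = call


def _calls(k, n):
    return [_Call("flexible")] * k + [_Call("rigid")] * (n - k)


class TestSiteChangeDistribution:
    def test_planted_counts(self):
        planted = [0, 1, 1, 2, 2, 2, 3, 3, 4, 5]
        pairs = {f"p{i}": _calls(k, 8) for i, k in enumerate(planted)}
        h = site_change_distribution(pairs)
        assert h.counts == {0: 1, 1: 2, 2: 3, 3: 2, 4: 1, 5: 1}
        assert h.cumulative[5] == pytest.approx(1.0)
        assert h.n_sites == 10

    def test_all_rigid_mass_at_zero(self):
        pairs = {f"p{i}": _calls(0, 6) for i in range(7)}
        h = site_change_distribution(pairs)
        assert h.counts == {7: 7} or h.counts == {0: 7}
        assert h.counts == {0: 7}

    def test_cumulative_monotone_to_one(self):
        pairs = {f"p{i}": _calls(i % 4, 6) for i in range(20)}
        h = site_change_distribution(pairs)
        cum = [h.cumulative[k] for k in sorted(h.cumulative)]
        assert all(b >= a for a, b in zip(cum, cum[1:]))
        assert cum[-1] == pytest.approx(1.0)

    def test_boolean_flag_input(self):
        pairs = {"a": [True, False, True], "b": [False, False, False]}
        h = site_change_distribution(pairs, method="delta_chi_60")
        assert h.counts == {0: 1, 2: 1}

    def test_pure_function_of_table(self):
        pairs = {f"p{i}": _calls(i % 3, 5) for i in range(9)}
        shuffled = dict(reversed(list(pairs.items())))
        assert site_change_distribution(pairs).counts == \
            site_change_distribution(shuffled).counts


class TestEntropyCorrelation:
    def test_exact_linear_gives_unit_correlation(self):
        scale = {t: ProbabilityEstimate(t, 1, 10, p, 0.0)
                 for t, p in [("SER", 0.1), ("LEU", 0.2), ("LYS", 0.4)]}
        ds = {"SER", "LEU", "LYS"}
        r, n = entropy_correlation(scale, {t: 2.0 * scale[t].p for t in ds})
        assert r == pytest.approx(1.0)
        r, _ = entropy_correlation(scale, {t: -scale[t].p for t in ds})
        assert r == pytest.approx(-1.0)

    def test_matches_hand_computed_covariance_ratio(self, rng):
        types = [f"T{i}" for i in range(10)]
        p = rng.uniform(0.05, 0.6, size=10)
        ds = rng.normal(size=10)
        scale = {t: float(v) for t, v in zip(types, p)}
        table = {t: float(v) for t, v in zip(types, ds)}
        r, n = entropy_correlation(scale, table)
        pc = p - p.mean()
        dc = ds - ds.mean()
        hand = float((pc * dc).sum() / np.sqrt((pc ** 2).sum() * (dc ** 2).sum()))
        assert r == pytest.approx(hand, abs=1e-12)
        assert n == 10

    def test_affine_invariance(self, rng):
        types = list("ABCDEF")
        p = dict(zip(types, rng.uniform(0, 1, 6)))
        ds = dict(zip(types, rng.normal(size=6)))
        r0, _ = entropy_correlation(p, ds)
        r1, _ = entropy_correlation(p, {t: 3.0 * v - 7.0 for t, v in ds.items()})
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_too_few_types_raise(self):
        with pytest.raises(ValueError):
            entropy_correlation({"A": 0.1, "B": 0.2}, {"A": 1.0, "B": 2.0})


class TestGroupComparison:
    def _frame(self, flex_vals, rigid_vals):
        rows = [{"call": "flexible", "res_type": "SER", "bfactor": v,
                 "sas_norm": v / 100} for v in flex_vals]
        rows += [{"call": "rigid", "res_type": "SER", "bfactor": v,
                  "sas_norm": v / 100} for v in rigid_vals]
        return pd.DataFrame(rows)

    def test_known_separation_rejected_at_alpha_001(self, rng):
        df = self._frame(rng.normal(30, 5, 100), rng.normal(20, 5, 100))
        out = compare_flexible_vs_rigid(df, quantities=("bfactor",))
        assert out[0].defined
        assert out[0].p_value < 0.01
        assert out[0].mean_flexible > out[0].mean_rigid

    def test_identical_groups_t_zero(self):
        vals = [10.0, 12.0, 14.0, 16.0]
        df = self._frame(vals, vals)
        out = compare_flexible_vs_rigid(df, quantities=("bfactor",))
        assert out[0].t_statistic == pytest.approx(0.0, abs=1e-12)
        assert out[0].p_value == pytest.approx(1.0, abs=1e-12)

    def test_tiny_group_is_undefined(self):
        df = self._frame([10.0], list(np.linspace(5, 25, 100)))
        out = compare_flexible_vs_rigid(df, quantities=("bfactor",))
        assert not out[0].defined

    def test_per_type_breakdown(self, rng):
        df = self._frame(rng.normal(30, 5, 20), rng.normal(20, 5, 20))
        out = compare_flexible_vs_rigid(df, quantities=("bfactor",),
                                        per_type=True)
        assert any(c.res_type == "SER" for c in out)


class _Assign:
    def __init__(self, rid):
        self.is_nr = rid == "NR"


class TestNrCounts:
    def test_planted_counts(self):
        pairs = [(_Assign("NR"), _Assign("x"))] * 5 + \
                [(_Assign("x"), _Assign("NR"))] * 3 + \
                [(_Assign("x"), _Assign("y"))] * 10
        assert nr_count_comparison(pairs) == (5, 3)

    def test_all_rotameric(self):
        assert nr_count_comparison([(_Assign("a"), _Assign("b"))] * 4) == (0, 0)


class TestMinimalRotationSummary:
    def _rec(self, key, crit, minrot, call="rigid"):
        return CriticalityRecord(key, 100.0 if crit else 0.0, crit, call, minrot)

    def test_planted_fraction(self):
        recs = [self._rec(i, True, i == 0) for i in range(4)]
        s = minimal_rotation_summary(recs)
        assert (s.n_critical, s.n_minimal) == (4, 1)
        assert s.fraction == pytest.approx(0.25)

    def test_no_critical_is_undefined(self):
        s = minimal_rotation_summary([self._rec(1, False, None)])
        assert s.fraction is None

    def test_printed_partition_arithmetic(self):
        # 37 small-rotation vs 133 large-rotation critical residues
        recs = [self._rec(("f", i), True, True, "flexible") for i in range(2)]
        recs += [self._rec(("r", i), True, True, "rigid") for i in range(35)]
        recs += [self._rec(("x", i), True, False, "flexible") for i in range(52)]
        recs += [self._rec(("y", i), True, False, "rigid") for i in range(81)]
        s = minimal_rotation_summary(recs)
        assert s.n_critical == 170
        assert s.n_minimal == 37
        assert s.fraction == pytest.approx(37 / 170)
        assert s.by_call["flexible"] == (54, 2)
        assert s.by_call["rigid"] == (116, 35)


def test_hbond_delta_fraction_table():
    from rotaflex.hbond import HBondDelta
    rows = [("flexible", HBondDelta(("A", 1, ""), water="loss")),
            ("flexible", HBondDelta(("A", 2, ""), water="loss")),
            ("rigid", HBondDelta(("A", 3, ""), protein="gain"))]
    table = hbond_delta_fractions(rows)
    assert table.loc[("flexible", "water"), "loss"] == pytest.approx(1.0)
    assert table.loc[("rigid", "protein"), "gain"] == pytest.approx(1.0)
    assert np.allclose(table.sum(axis=1), 1.0)
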