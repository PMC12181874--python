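"""Disproportionality statistics against an independent brute-force oracle.

The oracle below re-evaluates the four formulas from scratch (exact rational
arithmetic for the point estimates, plain ``math`` for the intervals) and is
kept independent of the package's vectorized implementation.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faersig.io import MeddraMap
from faersig.signals import (ContingencyTable, DisproportionalityAnalysis,
                             SignalResult, bcpnn_ic, build_contingency, ebgm,
                             evaluate_criteria, prr, ror, soc_aggregate)


# --- independent oracle -----------------------------------------------------

def oracle(a, b, c, d):
    n = a + b + c + d
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror_pt = Fraction(a) * d / (Fraction(b) * c)
    prr_pt = (Fraction(a) / (a + b)) / (Fraction(c) / (c + d))
    chi2 = Fraction((a * d - b * c) ** 2) * n / Fraction((a + b) * (c + d) * (a + c) * (b + d))
    oe = Fraction(a) * n / (Fraction(a + c) * (a + b))
    ic = math.log2(oe)
    v_ic = (1 / math.log(2)) ** 2 * (1 / a - 1 / (a + b) - 1 / (a + c) + 1 / n)
    return {
        "ror": float(ror_pt),
        "ror_lo": math.exp(math.log(ror_pt) - 1.96 * se),
        "ror_hi": math.exp(math.log(ror_pt) + 1.96 * se),
        "prr": float(prr_pt),
        "chi2": float(chi2),
        "ic": ic,
        "ic025": ic - 2 * math.sqrt(max(v_ic, 0.0)),
        "ebgm": float(oe),
        "ebgm05": math.exp(math.log(oe) - 1.96 * se),
    }


def random_tables(n, seed=12345, lo=1, hi=100_000):
    rng = np.random.Generator(np.random.Philox(seed))
    return rng.integers(lo, hi + 1, size=(n, 4)).tolist()  # python ints, no overflow


class TestPointEstimates:
    T = ContingencyTable(10, 90, 100, 9900)

    def test_worked_example(self):
        est, lo, hi = ror(self.T)
        assert est == pytest.approx(11.0, rel=1e-12)
        assert (lo, hi) == pytest.approx((5.5595149289, 21.7644887274), rel=1e-9)
        p, chi2 = prr(self.T)
        assert p == pytest.approx(10.0, rel=1e-12)
        assert chi2 == pytest.approx(74.44717444717445, rel=1e-12)
        ic, ic025 = bcpnn_ic(self.T)
        assert ic == pytest.approx(math.log2(9.18181818181818), rel=1e-12)
        e, e05 = ebgm(self.T)
        assert e == pytest.approx(9.181818181818182, rel=1e-12)
        assert e05 == pytest.approx(4.640586841474, rel=1e-9)

    @pytest.mark.parametrize("k", [1, 3, 250])
    def test_uniform_table_is_null(self, k):
        t = ContingencyTable(k, k, k, k)
        assert ror(t)[0] == pytest.approx(1.0)
        p, chi2 = prr(t)
        assert (p, chi2) == pytest.approx((1.0, 0.0))
        assert bcpnn_ic(t)[0] == pytest.approx(0.0)
        assert ebgm(t)[0] == pytest.approx(1.0)

    def test_prr_symmetry_when_margins_match(self):
        p, _ = prr(ContingencyTable(7, 13, 7, 13))
        assert p == pytest.approx(1.0)

    def test_ic_increases_in_a(self):
        ics = [bcpnn_ic(ContingencyTable(a, 50, 1000, 90000))[0] for a in (1, 5, 20)]
        assert ics == sorted(ics)

    def test_oracle_equivalence_on_random_tables(self):
        for a, b, c, d in random_tables(300):
            t = ContingencyTable(a, b, c, d)
            exp = oracle(a, b, c, d)
            assert ror(t)[0] == pytest.approx(exp["ror"], rel=1e-12)
            assert prr(t) == pytest.approx((exp["prr"], exp["chi2"]), rel=1e-12)
            assert bcpnn_ic(t) == pytest.approx((exp["ic"], exp["ic025"]), rel=1e-12)
            assert ebgm(t) == pytest.approx((exp["ebgm"], exp["ebgm05"]), rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(1, 100_000)] * 4))
    def test_ic_ebgm_identity_and_interval_symmetry(self, cells):
        t = ContingencyTable(*cells)
        ic, _ = bcpnn_ic(t)
        e, e05 = ebgm(t)
        assert 2 ** ic == pytest.approx(e, rel=1e-12)
        est, lo, hi = ror(t)
        assert est == pytest.approx(math.sqrt(lo * hi), rel=1e-10)
        # same log-scale symmetry for the EBGM bound: e05 = e^2 / e_hi
        se = math.sqrt(sum(1 / x for x in cells))
        assert e05 == pytest.approx(e * math.exp(-1.96 * se), rel=1e-10)

    def test_ror_at_least_prr_when_positively_associated(self):
        for a, b, c, d in random_tables(100, seed=99):
            if a * d >= b * c:
                t = ContingencyTable(a, b, c, d)
                assert ror(t)[0] >= prr(t)[0] - 1e-12
                assert prr(t)[0] >= 1.0 - 1e-12 or a * d == b * c


class TestZeroCells:
    def test_haldane_correction_applied_and_flagged(self):
        t = ContingencyTable(0, 10, 5, 100)
        corrected = t.corrected_copy()
        assert corrected.corrected
        assert (corrected.a, corrected.b) == (0.5, 10.5)
        assert corrected.case_count == 0
        est, lo, hi = ror(t)
        assert math.isfinite(est) and est > 0

    def test_no_correction_for_positive_tables(self):
        t = ContingencyTable(1, 1, 1, 1)
        assert t.corrected_copy() is t

    def test_disabled_correction_gives_nan(self):
        t = ContingencyTable(0, 10, 5, 100)
        assert math.isnan(ror(t, zero_cell="none")[0])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestBuildContingency:
    def test_definition(self):
        target = {f"t{i}": {"X"} if i < 10 else {"Y"} for i in range(100)}
        bg = {f"b{i}": {"X"} if i < 100 else {"Z"} for i in range(10_000)}
        t = build_contingency(target, bg, "X")
        assert (t.a, t.b, t.c, t.d) == (10, 90, 100, 9900)

    def test_empty_target(self):
        t = build_contingency({}, {"b1": {"X"}}, "X")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 1, 0)

    def test_report_level_counting(self):
        # a report listing the PT twice is a set; still contributes one
        t = build_contingency([{"X"}, {"X", "Y"}], [{"Y"}], "X")
        assert t.a == 2


class TestCriteria:
    def base(self, **kw):
        defaults = dict(pt="X", a=10, ror=5, ror_lo95=2, ror_hi95=10, prr=5,
                        chi2=30, ic=2, ic025=1, ebgm=5, ebgm05=3)
        defaults.update(kw)
        return SignalResult(**defaults)

    def test_all_pass(self):
        r = evaluate_criteria(self.base())
        assert (r.pass_ror, r.pass_prr, r.pass_bcpnn, r.pass_ebgm, r.is_signal) \
            == (True, True, True, True, True)

    @pytest.mark.parametrize("field,value,failing", [
        ("ror_lo95", 1.0, "pass_ror"),     # strict: bound exactly 1 fails
        ("ic025", 0.0, "pass_bcpnn"),      # strict
        ("ebgm05", 2.0, "pass_ebgm"),      # strict
    ])
    def test_strict_boundaries_fail(self, field, value, failing):
        r = evaluate_criteria(self.base(**{field: value}))
        assert getattr(r, failing) is False
        assert r.is_signal is False

    @pytest.mark.parametrize("field,value", [("prr", 2.0), ("chi2", 4.0), ("a", 3)])
    def test_non_strict_boundaries_pass(self, field, value):
        r = evaluate_criteria(self.base(**{field: value}))
        assert r.pass_prr is True

    def test_case_count_below_three_blocks_ror_and_prr(self):
        r = evaluate_criteria(self.base(a=2, ror=100, ror_lo95=50))
        assert r.pass_ror is False and r.pass_prr is False

    def test_worked_example_passes_all_four(self):
        t = ContingencyTable(10, 90, 100, 9900)
        est, lo, hi = ror(t)
        p, chi2 = prr(t)
        ic, ic025 = bcpnn_ic(t)
        e, e05 = ebgm(t)
        r = evaluate_criteria(SignalResult(pt="X", a=10, ror=est, ror_lo95=lo,
                                           ror_hi95=hi, prr=p, chi2=chi2, ic=ic,
                                           ic025=ic025, ebgm=e, ebgm05=e05))
        assert r.is_signal is True


class TestDetect:
    def test_empty_target_yields_empty_results(self):
        res = DisproportionalityAnalysis({}, {"b": {"X"}}).fit()
        assert len(res.frame) == 0 and len(res.signals) == 0

    def test_overlapping_report_ids_rejected(self):
        with pytest.raises(ValueError, match="share"):
            DisproportionalityAnalysis({"r": {"X"}}, {"r": {"Y"}})

    def test_single_planted_signal_flagged(self):
        rng = np.random.Generator(np.random.Philox(5))
        target = {f"t{i}": frozenset({"Hot"} if rng.random() < 0.3 else set()) | {"Base"}
                  for i in range(400)}
        bg = {f"b{i}": frozenset({"Hot"} if rng.random() < 0.02 else set()) | {"Base"}
              for i in range(20_000)}
        res = DisproportionalityAnalysis(target, bg).fit()
        assert list(res.signals["pt"]) == ["Hot"]

    def test_ranking_deterministic(self):
        target = {f"t{i}": {"A", "B"} for i in range(10)}
        bg = {f"b{i}": {"C"} for i in range(100)}
        res = DisproportionalityAnalysis(target, bg).fit()
        assert list(res.frame["pt"]) == ["A", "B"]  # equal a & ror -> lexicographic

    def test_scalar_and_vector_paths_agree(self):
        rng = np.random.Generator(np.random.Philox(11))
        pts = ["P1", "P2", "P3"]
        target = {f"t{i}": frozenset(p for p in pts if rng.random() < 0.4) or frozenset({"P1"})
                  for i in range(200)}
        bg = {f"b{i}": frozenset(p for p in pts if rng.random() < 0.2) or frozenset({"P2"})
              for i in range(2000)}
        res = DisproportionalityAnalysis(target, bg).fit()
        for _, row in res.frame.iterrows():
            t = build_contingency(target, bg, row["pt"])
            assert row["ror"] == pytest.approx(ror(t)[0], rel=1e-12)
            assert row["ic025"] == pytest.approx(bcpnn_ic(t)[1], rel=1e-12)
            assert row["ebgm05"] == pytest.approx(ebgm(t)[1], rel=1e-12)


class TestSocAggregate:
    MAP = MeddraMap({"A1": "Soc A", "A2": "Soc A", "B1": "Soc B"})

    def test_single_soc_has_proportion_one(self):
        out = soc_aggregate([{"A1"}, {"A2"}, {"A1", "A2"}], self.MAP)
        assert list(out["soc"]) == ["Soc A"]
        assert out.loc[0, "proportion_pct"] == pytest.approx(100.0)
        assert out.loc[0, "n_pt_reports"] == 4
        assert out.loc[0, "n_reports"] == 3

    def test_equal_counts_split_evenly(self):
        out = soc_aggregate([{"A1"}, {"B1"}], self.MAP)
        assert out["proportion_pct"].tolist() == pytest.approx([50.0, 50.0])

    def test_proportions_sum_to_100(self):
        out = soc_aggregate([{"A1", "B1"}, {"A2"}, {"B1", "Zzz"}], self.MAP)
        assert out["proportion_pct"].sum() == pytest.approx(100.0)
        assert "Unmapped" in set(out["soc"])
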