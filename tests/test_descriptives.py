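"""Characteristics table, onset computation/binning, Weibull fit, subgroups."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faersig.descriptives import (SubgroupSpec, WeibullOnsetModel,
                                  bin_onsets, characteristics_table,
                                  compute_onsets, round_half_up, subgroup_run,
                                  weibull_fit)
from faersig.preprocess import CaseSet


def make_caseset(reports):
    """CaseSet from dicts with keys pid, sex, age, occp, fda, event, event_prec,
    pts, outcomes, start (therapy start date or None)."""
    demo_rows, ther_rows = [], []
    pts, outcomes, seqs = {}, {}, {}
    for r in reports:
        pid = str(r["pid"])
        demo_rows.append({
            "primaryid": pid, "caseid": pid,
            "fda_dt": pd.Timestamp(r.get("fda", "2020-06-01")), "fda_dt_prec": "day",
            "event_dt": pd.Timestamp(r["event"]) if r.get("event") else pd.NaT,
            "event_dt_prec": r.get("event_prec", "day" if r.get("event") else None),
            "sex": r.get("sex", "UNK"), "age_years": r.get("age", float("nan")),
            "occp_cod": r.get("occp"), "reporter_country": r.get("country", "Not Specified"),
        })
        pts[pid] = frozenset(r.get("pts", {"Arthralgia"}))
        if r.get("outcomes"):
            outcomes[pid] = frozenset(r["outcomes"])
        seqs[pid] = ["1"]
        if r.get("start"):
            ther_rows.append({"primaryid": pid, "dsg_drug_seq": "1",
                              "start_dt": pd.Timestamp(r["start"]), "start_dt_prec": "day"})
    demo = pd.DataFrame(demo_rows)
    ther = pd.DataFrame(ther_rows, columns=["primaryid", "dsg_drug_seq",
                                            "start_dt", "start_dt_prec"])
    return CaseSet(demo=demo, pts=pts, outcomes=outcomes, target_drug_seqs=seqs,
                   therapy_starts=ther, provenance=[])


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (41.174, 41.2), (41.15, 41.2), (41.1499, 41.1), (0.049, 0.0), (0.05, 0.1),
    ])
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x) == expected


class TestCharacteristicsTable:
    def test_sex_percentages_and_outcome_denominator(self):
        reports = ([{"pid": i, "sex": "F"} for i in range(3)]
                   + [{"pid": 10 + i, "sex": "M"} for i in range(2)])
        reports[0]["outcomes"] = {"HO", "OT"}   # two entries from one report
        cs = make_caseset(reports)
        tbl = characteristics_table(cs)
        sex = tbl[tbl["block"] == "Gender"].set_index("label")
        assert sex.loc["Female", "count"] == 3
        assert sex.loc["Female", "pct"] == 60.0
        out = tbl[tbl["block"] == "Outcomes"].set_index("label")
        # denominator = 2 coded entries + 4 reports without outcomes = 6
        assert out["count"].sum() == 6
        assert out.loc["Hospitalization-Initial or Prolonged", "pct"] == round_half_up(100 / 6)

    def test_single_sex_is_100_percent(self):
        cs = make_caseset([{"pid": 1, "sex": "F"}, {"pid": 2, "sex": "F"}])
        tbl = characteristics_table(cs)
        sex = tbl[tbl["block"] == "Gender"]
        assert list(sex["label"]) == ["Female"] and list(sex["pct"]) == [100.0]

    def test_block_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        reports = [{"pid": i, "sex": rng.choice(["F", "M", "UNK"]),
                    "age": float(rng.integers(5, 80)) if rng.random() > 0.3 else None,
                    "occp": rng.choice(["CN", "MD", None])}
                   for i in range(57)]
        tbl = characteristics_table(make_caseset(reports))
        for block, g in tbl.groupby("block"):
            assert g["pct"].sum() == pytest.approx(100.0, abs=0.15), block

    def test_age_bin_presets(self):
        cs = make_caseset([{"pid": 1, "age": 17.0}, {"pid": 2, "age": 44.0},
                           {"pid": 3, "age": 64.0}, {"pid": 4, "age": 70.0}])
        t3 = characteristics_table(cs, age_bins="table3")
        labels = set(t3[t3["block"] == "Age (years)"]["label"])
        assert {"< 18", ">= 18, < 45", ">= 45, < 65", ">= 65"} <= labels
        sub = characteristics_table(cs, age_bins="subgroup")
        labels = set(sub[sub["block"] == "Age (years)"]["label"])
        assert {"< 18", ">= 18, < 65", ">= 65"} <= labels


class TestOnsets:
    def test_basic_date_arithmetic(self):
        cs = make_caseset([{"pid": 1, "start": "2020-01-01", "event": "2020-01-16"}])
        onsets, n_missing = compute_onsets(cs)
        assert list(onsets["days"]) == [15] and n_missing == 0

    def test_event_before_start_excluded(self):
        cs = make_caseset([{"pid": 1, "start": "2020-02-01", "event": "2020-01-16"}])
        onsets, n_missing = compute_onsets(cs)
        assert len(onsets) == 0 and n_missing == 1

    def test_partial_event_date_excluded(self):
        cs = make_caseset([{"pid": 1, "start": "2020-01-01", "event": "2020-01-01",
                            "event_prec": "month"}])
        onsets, n_missing = compute_onsets(cs)
        assert len(onsets) == 0 and n_missing == 1

    def test_missing_therapy_start_excluded(self):
        cs = make_caseset([{"pid": 1, "event": "2020-01-16"}])
        assert compute_onsets(cs)[1] == 1

    def test_earliest_day_precise_start_used(self):
        cs = make_caseset([{"pid": 1, "start": "2020-01-10", "event": "2020-01-16"}])
        extra = pd.DataFrame([{"primaryid": "1", "dsg_drug_seq": "1",
                               "start_dt": pd.Timestamp("2020-01-04"),
                               "start_dt_prec": "day"}])
        cs.therapy_starts = pd.concat([cs.therapy_starts, extra], ignore_index=True)
        assert list(compute_onsets(cs)[0]["days"]) == [12]


class TestBinOnsets:
    def test_boundaries_closed_as_printed(self):
        frame = pd.DataFrame({"days": [0, 30, 31, 360, 361]})
        tbl = bin_onsets(frame).set_index("bin")
        assert tbl.loc["0-30 d", "count"] == 2
        assert tbl.loc["31-60 d", "count"] == 1
        assert tbl.loc["181-360 d", "count"] == 1
        assert tbl.loc["> 360 d", "count"] == 1

    def test_counts_plus_missing_conserve_total(self):
        frame = pd.DataFrame({"days": [5, 45, 400]})
        tbl = bin_onsets(frame, total_reports=10, n_missing=7)
        assert tbl["count"].sum() == 10
        assert tbl["pct"].sum() == pytest.approx(100.0, abs=0.3)

    def test_empty_onsets(self):
        tbl = bin_onsets(pd.DataFrame({"days": []}), total_reports=4, n_missing=4)
        assert math.isnan(tbl.attrs["median"])
        assert tbl.set_index("bin").loc["Not Specified or missing", "count"] == 4


class TestWeibull:
    def draws(self, shape, scale, n=1000, seed=0):
        rng = np.random.Generator(np.random.Philox(seed))
        return rng.weibull(shape, size=n) * scale

    def test_exponential_classified_random(self):
        fit = WeibullOnsetModel(self.draws(1.0, 30.0)).fit()
        assert fit.shape_lo95 < 1.0 < fit.shape_hi95
        assert fit.classification == "random"

    def test_early_failure_recovery(self):
        fit = WeibullOnsetModel(self.draws(0.6, 50.0)).fit()
        assert 0.55 <= fit.shape <= 0.65
        assert fit.classification == "early failure"

    def test_wear_out_classification(self):
        fit = WeibullOnsetModel(self.draws(1.5, 50.0)).fit()
        assert fit.classification == "wear-out"

    def test_scale_equivariance(self):
        x = self.draws(0.8, 20.0, n=500)
        f1 = WeibullOnsetModel(x).fit()
        f2 = WeibullOnsetModel(2 * x).fit()
        assert f2.shape == pytest.approx(f1.shape, rel=1e-6)
        assert f2.scale == pytest.approx(2 * f1.scale, rel=1e-6)

    def test_agrees_with_scipy_mle(self):
        x = self.draws(0.9, 40.0, n=400, seed=9)
        fit = WeibullOnsetModel(x).fit()
        shape_sp, _, scale_sp = stats.weibull_min.fit(x, floc=0)
        assert fit.shape == pytest.approx(shape_sp, rel=1e-4)
        assert fit.scale == pytest.approx(scale_sp, rel=1e-4)

    def test_zero_days_shifted_not_dropped(self):
        x = np.concatenate([[0.0, 0.0], self.draws(0.8, 30.0, n=200)])
        fit = WeibullOnsetModel(x).fit()
        assert fit.n_used == 202

    def test_too_few_or_degenerate_data_raises(self):
        with pytest.raises(ValueError, match="at least"):
            WeibullOnsetModel([1, 2, 3]).fit()
        with pytest.raises(ValueError, match="degenerate"):
            WeibullOnsetModel([5.0] * 50).fit()

    def test_ci_bounds_positive_and_ordered(self):
        fit = weibull_fit(pd.DataFrame({"days": self.draws(0.7, 25.0)}))
        assert 0 < fit.shape_lo95 < fit.shape < fit.shape_hi95
        assert 0 < fit.scale_lo95 < fit.scale < fit.scale_hi95


class TestSubgroups:
    def caseset_and_background(self):
        reports = []
        for i in range(40):
            sex = "F" if i % 2 else "M"
            # males get systematically longer onsets
            days = 5 if sex == "F" else 50
            reports.append({"pid": i, "sex": sex, "pts": {"Arthralgia"},
                            "start": "2020-01-01",
                            "event": str(pd.Timestamp("2020-01-01")
                                         + pd.Timedelta(days=days)).split()[0]})
        cs = make_caseset(reports)
        bg_demo = pd.DataFrame([
            {"primaryid": f"b{i}", "sex": "F" if i % 2 else "M",
             "age_years": 30.0, "occp_cod": "CN"} for i in range(400)])
        bg_pts = {f"b{i}": frozenset({"Headache"}) for i in range(400)}
        return cs, bg_demo, bg_pts

    def test_partition_conserves_cases(self):
        cs, bg_demo, bg_pts = self.caseset_and_background()
        runs = subgroup_run(cs, bg_demo, bg_pts, SubgroupSpec("sex"))
        assert sum(e["n_cases"] for e in runs.values()) == len(cs)

    def test_stratum_medians_recover_planted_ordering(self):
        cs, bg_demo, bg_pts = self.caseset_and_background()
        runs = subgroup_run(cs, bg_demo, bg_pts, SubgroupSpec("sex"))
        assert runs["Male"]["onset_median"] > runs["Female"]["onset_median"]

    def test_single_stratum_equals_unstratified(self):
        from faersig.signals import detect_signals
        cs, bg_demo, bg_pts = self.caseset_and_background()
        spec = SubgroupSpec("occp_cod", bins={"Everyone": {None}})
        # no occp codes -> no strata; instead use a sex spec collapsing levels
        spec = SubgroupSpec("age_years", bins=[(0, None, "All")])
        cs.demo["age_years"] = 30.0
        runs = subgroup_run(cs, bg_demo, bg_pts, spec)
        full = detect_signals(cs, bg_pts)
        assert list(runs.keys()) == ["All"]
        pd.testing.assert_frame_equal(
            runs["All"]["results"].frame.drop(columns="soc"),
            full.frame.drop(columns="soc"))

    def test_empty_stratum_yields_empty_results(self):
        cs, bg_demo, bg_pts = self.caseset_and_background()
        cs.demo["sex"] = "F"
        runs = subgroup_run(cs, bg_demo, bg_pts, SubgroupSpec("sex"))
        assert set(runs) == {"Female"}
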