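"""Descriptive tables, time-to-onset analysis, and subgroup runs.

Covers the clinical-characteristics table (counts and percentages for sex,
age, report year, reporter occupation, country, outcomes and onset bins),
time-to-onset extraction and binning, the Weibull shape-parameter (WSP)
analysis of onset times, and subgroup-stratified signal detection.

The WSP analysis fits a two-parameter Weibull distribution to the observed
onset delays by maximum likelihood.  Its shape parameter beta classifies how
the hazard of the adverse event changes with time on drug: beta < 1 means a
decreasing hazard ("early failure" — events cluster just after treatment
start), beta = 1 a constant hazard (memoryless, as for events unrelated to
treatment duration), beta > 1 an increasing hazard ("wear-out").  The
classification uses the 95% confidence interval of beta, not the point
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import optimize

from .signals import CriteriaConfig, DisproportionalityResults, detect_signals

__all__ = [
    "OCCP_LABELS",
    "ONSET_BINS",
    "AGE_BIN_PRESETS",
    "SubgroupSpec",
    "WeibullFit",
    "WeibullOnsetModel",
    "characteristics_table",
    "compute_onsets",
    "bin_onsets",
    "weibull_fit",
    "subgroup_run",
    "round_half_up",
]

OCCP_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "HP": "Other health-professional",
    "OT": "Other health-professional",
    "LW": "Lawyer",
    "RN": "Other health-professional",
}

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization-Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention",
    "OT": "Other Serious (Important Medical Event)",
}

#: Closed onset-day bins, as conventionally tabulated.
ONSET_BINS = [(0, 30), (31, 60), (61, 90), (91, 120), (121, 150),
              (151, 180), (181, 360), (361, None)]

AGE_BIN_PRESETS = {
    # subgroup-analysis default
    "subgroup": [(0, 18, "< 18"), (18, 65, ">= 18, < 65"), (65, None, ">= 65")],
    # characteristics-table alternative
    "table3": [(0, 18, "< 18"), (18, 45, ">= 18, < 45"), (45, 65, ">= 45, < 65"),
               (65, None, ">= 65")],
}

NOT_SPECIFIED = "Not Specified"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 41.15 -> 41.2, not banker's 41.1)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, denom: int) -> float:
    return round_half_up(100.0 * count / denom) if denom else math.nan


def _age_label(age: float, bins) -> str:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return NOT_SPECIFIED
    for lo, hi, label in bins:
        if age >= lo and (hi is None or age < hi):
            return label
    return NOT_SPECIFIED


def characteristics_table(caseset, age_bins: str | list = "table3") -> pd.DataFrame:
    """Counts and percentages of report characteristics, block by block.

    Percentages use the total report count as denominator for every block
    except Outcomes, whose denominator is the total number of outcome
    entries (a report may carry several outcome codes; one with none counts
    as a single "Not Specified" entry).  Rounding is half-up to 1 decimal.
    """
    bins = AGE_BIN_PRESETS[age_bins] if isinstance(age_bins, str) else age_bins
    demo = caseset.demo
    total = len(demo)
    rows: list[dict] = []

    def block(name: str, counts: dict, denom: int, order=None):
        labels = order if order is not None else sorted(counts, key=lambda k: (-counts[k], k))
        for label in labels:
            if label not in counts:
                continue
            rows.append({"block": name, "label": label, "count": counts[label],
                         "pct": _pct(counts[label], denom)})

    sex_counts = demo["sex"].map({"F": "Female", "M": "Male"}).fillna(NOT_SPECIFIED) \
                            .replace({"UNK": NOT_SPECIFIED}).value_counts().to_dict()
    block("Gender", sex_counts, total, ["Female", "Male", NOT_SPECIFIED])

    age_counts = demo["age_years"].map(lambda a: _age_label(a, bins)).value_counts().to_dict()
    block("Age (years)", age_counts, total,
          [b[2] for b in bins] + [NOT_SPECIFIED])

    year_counts = demo["fda_dt"].dt.year.astype(str).value_counts().to_dict()
    block("Reported year", year_counts, total, sorted(year_counts, reverse=True))

    occ_counts = demo["occp_cod"].map(lambda c: OCCP_LABELS.get(c, NOT_SPECIFIED)
                                      if c else NOT_SPECIFIED).value_counts().to_dict()
    block("Reporters", occ_counts, total)

    country_counts = demo["reporter_country"].value_counts().to_dict()
    block("Report countries", country_counts, total)

    outcome_counts: dict[str, int] = {}
    n_entries = 0
    for pid in demo["primaryid"]:
        codes = caseset.outcomes.get(pid, frozenset())
        if codes:
            for code in codes:
                label = OUTCOME_LABELS.get(code, code)
                outcome_counts[label] = outcome_counts.get(label, 0) + 1
                n_entries += 1
        else:
            outcome_counts[NOT_SPECIFIED] = outcome_counts.get(NOT_SPECIFIED, 0) + 1
            n_entries += 1
    block("Outcomes", outcome_counts, n_entries)

    onsets, n_missing = compute_onsets(caseset)
    onset_tbl = bin_onsets(onsets, total_reports=total, n_missing=n_missing)
    for _, r in onset_tbl.iterrows():
        rows.append({"block": "Time to onset", "label": r["bin"],
                     "count": r["count"], "pct": r["pct"]})
    return pd.DataFrame(rows)


def compute_onsets(caseset) -> tuple[pd.DataFrame, int]:
    """Days from target-drug therapy start to adverse-event onset, per report.

    The clock starts at the earliest *day-precise* therapy start date of the
    target drug's rows; the event date must also be day-precise.  Reports
    with either date missing or partial, or with a negative difference, are
    excluded and counted in the returned missing total.

    Returns ``(frame, n_missing)`` where frame has columns primaryid, days,
    sex, age_years, occp_cod.
    """
    demo = caseset.demo.set_index("primaryid")
    ther = caseset.therapy_starts
    day_starts: dict[str, pd.Timestamp] = {}
    if len(ther):
        ok = (ther["start_dt_prec"] == "day") & ther["start_dt"].notna()
        for pid, g in ther[ok].groupby("primaryid"):
            seqs = set(caseset.target_drug_seqs.get(pid, []))
            g2 = g[g["dsg_drug_seq"].isin(seqs)] if seqs else g.iloc[0:0]
            if len(g2):
                day_starts[pid] = g2["start_dt"].min()

    rows = []
    n_missing = 0
    for pid in caseset.demo["primaryid"]:
        d = demo.loc[pid]
        start = day_starts.get(pid)
        if start is None or d["event_dt_prec"] != "day" or pd.isna(d["event_dt"]):
            n_missing += 1
            continue
        days = int((d["event_dt"] - start).days)
        if days < 0:
            n_missing += 1
            continue
        rows.append({"primaryid": pid, "days": days, "sex": d["sex"],
                     "age_years": d["age_years"], "occp_cod": d["occp_cod"]})
    frame = pd.DataFrame(rows, columns=["primaryid", "days", "sex", "age_years", "occp_cod"])
    return frame, n_missing


def bin_onsets(onsets: pd.DataFrame, total_reports: int | None = None,
               n_missing: int | None = None) -> pd.DataFrame:
    """Binned onset counts with percentages, median and min-max range.

    Bins are closed day intervals (0-30, 31-60, ..., 181-360, > 360) plus a
    missing row; percentages are over the total report count so that bins
    plus missing sum to 100%.
    """
    days = onsets["days"].to_numpy() if len(onsets) else np.array([], dtype=int)
    if n_missing is None:
        n_missing = 0
    if total_reports is None:
        total_reports = len(days) + n_missing
    rows = []
    for lo, hi in ONSET_BINS:
        if hi is None:
            cnt = int((days >= lo).sum())
            label = f"> {lo - 1} d"
        else:
            cnt = int(((days >= lo) & (days <= hi)).sum())
            label = f"{lo}-{hi} d"
        rows.append({"bin": label, "count": cnt, "pct": _pct(cnt, total_reports)})
    rows.append({"bin": "Not Specified or missing", "count": n_missing,
                 "pct": _pct(n_missing, total_reports)})
    out = pd.DataFrame(rows)
    out.attrs["median"] = float(np.median(days)) if len(days) else math.nan
    out.attrs["min"] = float(days.min()) if len(days) else math.nan
    out.attrs["max"] = float(days.max()) if len(days) else math.nan
    out.attrs["n"] = int(len(days))
    return out


@dataclass
class WeibullFit:
    """Weibull shape/scale estimates, CIs and hazard classification."""

    shape: float
    shape_lo95: float
    shape_hi95: float
    scale: float
    scale_lo95: float
    scale_hi95: float
    n_used: int
    loglik: float
    classification: str  # "early failure" | "random" | "wear-out"

    def summary(self) -> str:
        return (
            "Weibull shape-parameter (WSP) analysis of time to onset\n"
            f"  n used:  {self.n_used}\n"
            f"  shape beta:  {self.shape:.3f}  (95% CI {self.shape_lo95:.3f}-{self.shape_hi95:.3f})\n"
            f"  scale alpha: {self.scale:.1f} days  (95% CI {self.scale_lo95:.1f}-{self.scale_hi95:.1f})\n"
            f"  log-likelihood: {self.loglik:.2f}\n"
            f"  hazard classification: {self.classification}"
        )


class WeibullOnsetModel:
    """Maximum-likelihood two-parameter Weibull model for onset delays.

    Zero-day onsets (event on the start date) are shifted by +0.5 day before
    fitting, since the Weibull log-likelihood requires positive support;
    binning elsewhere always uses the raw integer days.

    The shape MLE solves the standard profile score equation by bracketed
    root finding; 95% CIs come from the observed Fisher information on the
    log-parameters (normal approximation, then exponentiated), which keeps
    the bounds positive.

    >>> res = WeibullOnsetModel(days).fit()
    >>> res.shape, res.classification
    """

    min_n = 10

    def __init__(self, days):
        raw = np.asarray(days, dtype=float)
        raw = raw[~np.isnan(raw)]
        if np.any(raw < 0):
            raise ValueError("onset days must be >= 0")
        self.data = np.where(raw == 0.0, 0.5, raw)

    def fit(self) -> WeibullFit:
        x = self.data
        n = len(x)
        if n < self.min_n:
            raise ValueError(f"need at least {self.min_n} usable onsets, got {n}")
        if np.allclose(x, x[0]):
            raise ValueError("degenerate onset data: all values equal")
        logx = np.log(x)
        mean_logx = logx.mean()

        def score(beta):  # d/dbeta profile log-likelihood = 0 at the MLE
            xb = x ** beta
            return (xb * logx).sum() / xb.sum() - 1.0 / beta - mean_logx

        lo, hi = 1e-3, 1.0
        while score(hi) < 0 and hi < 1e3:
            hi *= 2.0
        beta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14)
        alpha = (np.mean(x ** beta)) ** (1.0 / beta)
        loglik = float(n * (math.log(beta) - beta * math.log(alpha))
                       + (beta - 1.0) * logx.sum() - np.sum((x / alpha) ** beta))

        cov = self._cov_log_params(beta, alpha)
        se_logb, se_loga = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        b_lo, b_hi = beta * math.exp(-1.96 * se_logb), beta * math.exp(1.96 * se_logb)
        a_lo, a_hi = alpha * math.exp(-1.96 * se_loga), alpha * math.exp(1.96 * se_loga)
        if b_hi < 1.0:
            cls = "early failure"
        elif b_lo > 1.0:
            cls = "wear-out"
        else:
            cls = "random"
        return WeibullFit(beta, b_lo, b_hi, alpha, a_lo, a_hi, n, loglik, cls)

    def _nll(self, theta) -> float:
        beta, alpha = math.exp(theta[0]), math.exp(theta[1])
        x = self.data
        z = (x / alpha) ** beta
        return float(-(len(x) * (math.log(beta) - beta * math.log(alpha))
                       + (beta - 1.0) * np.log(x).sum() - z.sum()))

    def _cov_log_params(self, beta: float, alpha: float) -> np.ndarray:
        # observed information: central-difference Hessian of the negative
        # log-likelihood in (log beta, log alpha)
        theta = np.array([math.log(beta), math.log(alpha)])
        h = 1e-4
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                e_i = np.eye(2)[i] * h
                e_j = np.eye(2)[j] * h
                H[i, j] = (self._nll(theta + e_i + e_j) - self._nll(theta + e_i - e_j)
                           - self._nll(theta - e_i + e_j) + self._nll(theta - e_i - e_j)) / (4 * h * h)
        return np.linalg.inv(H)


def weibull_fit(onsets) -> WeibullFit:
    """Fit the WSP model to an onset table or array of days."""
    days = onsets["days"] if isinstance(onsets, pd.DataFrame) else onsets
    return WeibullOnsetModel(days).fit()


@dataclass
class SubgroupSpec:
    """How to stratify reports: by sex, age bin, or reporter class."""

    field: str  # "sex" | "age_years" | "occp_cod"
    bins: list | dict | None = None  # age: (lo, hi, label) triples; occp: label -> codes

    def labels(self, demo: pd.DataFrame) -> pd.Series:
        """Stratum label per report; None where the field is missing."""
        if self.field == "sex":
            return demo["sex"].map({"F": "Female", "M": "Male"})
        if self.field == "age_years":
            bins = self.bins or AGE_BIN_PRESETS["subgroup"]
            return demo["age_years"].map(
                lambda a: None if (a is None or (isinstance(a, float) and math.isnan(a)))
                else _age_label(a, bins))
        if self.field == "occp_cod":
            groups = self.bins or {
                "Consumer": {"CN"},
                "Health professional": {"MD", "PH", "HP", "OT", "RN"},
            }
            code_to_label = {code: lbl for lbl, codes in groups.items() for code in codes}
            return demo["occp_cod"].map(lambda c: code_to_label.get(c))
        raise ValueError(f"unknown subgroup field {self.field!r}")


def subgroup_run(caseset, background_demo: pd.DataFrame, background_pts: dict,
                 spec: SubgroupSpec, meddra_map=None,
                 criteria: CriteriaConfig | None = None) -> dict:
    """Re-run signal detection and onset summaries within each stratum.

    The background is restricted to the *same* stratum so that stratum RORs
    are internally comparable.  Strata with zero target cases yield empty
    results rather than errors.

    Returns ``{stratum label: {"results": DisproportionalityResults,
    "n_cases": int, "onset_median": float, "onset_q1": float,
    "onset_q3": float, "onset_min": float, "onset_max": float,
    "n_onsets": int}}``.
    """
    target_labels = spec.labels(caseset.demo)
    bg_labels = spec.labels(background_demo)
    bg_by_stratum: dict = {}
    for pid, label in zip(background_demo["primaryid"], bg_labels):
        if label is not None and pid in background_pts:
            bg_by_stratum.setdefault(label, {})[pid] = background_pts[pid]

    onsets, _ = compute_onsets(caseset)
    onset_by_pid = dict(zip(onsets["primaryid"], onsets["days"]))

    out: dict = {}
    strata = [s for s in pd.unique(target_labels.dropna())]
    for stratum in sorted(strata, key=str):
        ids = caseset.demo.loc[target_labels == stratum, "primaryid"]
        sub = caseset.subset(ids)
        res = detect_signals(sub, bg_by_stratum.get(stratum, {}),
                             meddra_map=meddra_map, criteria=criteria)
        days = np.array([onset_by_pid[p] for p in ids if p in onset_by_pid], dtype=float)
        entry = {
            "results": res,
            "n_cases": len(sub),
            "n_onsets": int(len(days)),
            "onset_median": float(np.median(days)) if len(days) else math.nan,
            "onset_q1": float(np.percentile(days, 25)) if len(days) else math.nan,
            "onset_q3": float(np.percentile(days, 75)) if len(days) else math.nan,
            "onset_min": float(days.min()) if len(days) else math.nan,
            "onset_max": float(days.max()) if len(days) else math.nan,
        }
        out[stratum] = entry
    return out
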