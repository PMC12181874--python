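"""Disproportionality statistics for spontaneous-report signal detection.

For each adverse-event preferred term (PT), reports are cross-classified
against the target drug in a 2x2 table::

                      target PT   other PTs
    target drug           a           b
    other drugs           c           d        n = a + b + c + d

and four screening statistics are computed on it:

* **ROR** (reporting odds ratio) ``ad/(bc)`` with the standard log-normal
  95% interval ``exp(ln ROR ± 1.96 sqrt(1/a+1/b+1/c+1/d))``;
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-squared ``(ad-bc)^2 n / [(a+b)(c+d)(a+c)(b+d)]`` (no
  continuity correction);
* **IC** (BCPNN information component) ``log2[a n / ((a+c)(a+b))]`` with
  lower bound ``IC − 2 sqrt(V_IC)``, where ``V_IC`` is the delta-method
  variance ``(1/ln 2)^2 (1/a − 1/(a+b) − 1/(a+c) + 1/n)``;
* **EBGM**, here the crude observed/expected relative reporting ratio
  ``a n / ((a+c)(a+b))`` (identical to ``2^IC`` by construction; no
  gamma-Poisson shrinkage) with log-normal lower bound EBGM05.

A PT is a *signal* only when all four criteria hold simultaneously:
ROR lower bound > 1 with a ≥ 3; PRR ≥ 2 with chi2 ≥ 4 and a ≥ 3;
IC025 > 0; EBGM05 > 2.

Counting is report-level: a report mentioning a PT twice contributes one to
``a``.  Tables with a zero cell receive the Haldane–Anscombe correction
(+0.5 to all four cells, that table only) and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from collections import Counter

import numpy as np
import pandas as pd

from .io import MeddraMap

__all__ = [
    "ContingencyTable",
    "CriteriaConfig",
    "SignalResult",
    "DisproportionalityAnalysis",
    "DisproportionalityResults",
    "build_contingency",
    "ror",
    "prr",
    "bcpnn_ic",
    "ebgm",
    "evaluate_criteria",
    "detect_signals",
    "soc_aggregate",
]

_LN2_SQ_INV = 1.0 / math.log(2.0) ** 2


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d report counts of one drug-PT pair.

    ``corrected`` marks a table to which the Haldane–Anscombe +0.5 was
    applied (any raw cell zero); ``a_raw`` keeps the uncorrected case count
    used by the N >= 3 criteria.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False
    a_raw: float | None = None

    def __post_init__(self):
        # float cells: keeps products like (ad-bc)^2 * n out of int64 overflow
        for name in ("a", "b", "c", "d"):
            cell = float(getattr(self, name))
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")
            object.__setattr__(self, name, cell)

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def case_count(self) -> float:
        return self.a if self.a_raw is None else self.a_raw

    def corrected_copy(self) -> "ContingencyTable":
        """Haldane–Anscombe correction if any cell is zero, else self."""
        if min(self.a, self.b, self.c, self.d) > 0:
            return self
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5,
                                self.d + 0.5, corrected=True, a_raw=self.a)


@dataclass(frozen=True)
class CriteriaConfig:
    """Joint screening thresholds (strict vs non-strict exactly as stated)."""

    ror_lo_gt: float = 1.0   # ROR 95% lower bound > this (strict)
    min_n: int = 3           # case count a >= this (ROR and PRR rules)
    prr_min: float = 2.0     # PRR >= this
    chi2_min: float = 4.0    # chi2 >= this
    ic025_gt: float = 0.0    # IC025 > this (strict)
    ebgm05_gt: float = 2.0   # EBGM05 > this (strict)


@dataclass
class SignalResult:
    """All four statistics and pass flags for one PT."""

    pt: str
    soc: str = MeddraMap.UNMAPPED
    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0
    ror: float = math.nan
    ror_lo95: float = math.nan
    ror_hi95: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    corrected: bool = False
    pass_ror: bool = False
    pass_prr: bool = False
    pass_bcpnn: bool = False
    pass_ebgm: bool = False
    is_signal: bool = False


def build_contingency(target_pts, background_pts, pt: str) -> ContingencyTable:
    """2x2 table for one PT from report-level PT sets.

    ``target_pts`` / ``background_pts`` are mappings (or iterables) of PT
    sets, one per report; the two report collections must be disjoint.
    A report listing the PT twice has it once in its set, so contributes 1.
    """
    tsets = list(target_pts.values()) if hasattr(target_pts, "values") else list(target_pts)
    bsets = list(background_pts.values()) if hasattr(background_pts, "values") else list(background_pts)
    a = sum(1 for s in tsets if pt in s)
    c = sum(1 for s in bsets if pt in s)
    return ContingencyTable(a, len(tsets) - a, c, len(bsets) - c)


def _interval(est: float, a, b, c, d) -> tuple[float, float]:
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(math.log(est) - 1.96 * se), math.exp(math.log(est) + 1.96 * se)


def ror(t: ContingencyTable, zero_cell: str = "haldane") -> tuple[float, float, float]:
    """Reporting odds ratio with its log-normal 95% interval."""
    t = _effective(t, zero_cell)
    if t is None:
        return math.nan, math.nan, math.nan
    est = (t.a * t.d) / (t.b * t.c)
    lo, hi = _interval(est, t.a, t.b, t.c, t.d)
    return est, lo, hi


def prr(t: ContingencyTable, zero_cell: str = "haldane") -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-squared."""
    t = _effective(t, zero_cell)
    if t is None:
        return math.nan, math.nan
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    est = (a / (a + b)) / (c / (c + d))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    return est, chi2


def bcpnn_ic(t: ContingencyTable, zero_cell: str = "haldane") -> tuple[float, float]:
    """Information component and its lower interval bound IC − 2 sqrt(V_IC)."""
    t = _effective(t, zero_cell)
    if t is None:
        return math.nan, math.nan
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    ic = math.log2(a * n / ((a + c) * (a + b)))
    v = _LN2_SQ_INV * (1 / a - 1 / (a + b) - 1 / (a + c) + 1 / n)
    return ic, ic - 2.0 * math.sqrt(max(v, 0.0))


def ebgm(t: ContingencyTable, zero_cell: str = "haldane") -> tuple[float, float]:
    """Crude observed/expected relative reporting ratio and its lower bound."""
    t = _effective(t, zero_cell)
    if t is None:
        return math.nan, math.nan
    a, b, c, d = t.a, t.b, t.c, t.d
    est = a * (a + b + c + d) / ((a + c) * (a + b))
    lo, _ = _interval(est, a, b, c, d)
    return est, lo


def _effective(t: ContingencyTable, zero_cell: str) -> ContingencyTable | None:
    if zero_cell == "haldane":
        t = t.corrected_copy()
    if min(t.a, t.b, t.c, t.d) <= 0:
        return None  # undefined without correction; caller flags & excludes
    return t


def evaluate_criteria(r: SignalResult, criteria: CriteriaConfig | None = None) -> SignalResult:
    """Return a copy of ``r`` with the four pass flags and the joint flag set."""
    c = criteria or CriteriaConfig()
    ok = lambda x: not math.isnan(x)  # noqa: E731
    pass_ror = ok(r.ror_lo95) and r.ror_lo95 > c.ror_lo_gt and r.a >= c.min_n
    pass_prr = (ok(r.prr) and ok(r.chi2) and r.prr >= c.prr_min
                and r.chi2 >= c.chi2_min and r.a >= c.min_n)
    pass_bcpnn = ok(r.ic025) and r.ic025 > c.ic025_gt
    pass_ebgm = ok(r.ebgm05) and r.ebgm05 > c.ebgm05_gt
    return replace(r, pass_ror=pass_ror, pass_prr=pass_prr, pass_bcpnn=pass_bcpnn,
                   pass_ebgm=pass_ebgm,
                   is_signal=pass_ror and pass_prr and pass_bcpnn and pass_ebgm)


# ---------------------------------------------------------------------------
# model / results


class DisproportionalityAnalysis:
    """Four-algorithm disproportionality screen over every PT in the target set.

    Parameters
    ----------
    target_pts, background_pts : mapping of report id -> set of PTs
        Report-level PT sets for the target drug and for all other drugs
        (disjoint report collections).
    meddra_map : MeddraMap, optional
        PT -> System Organ Class lookup used to annotate results.
    criteria : CriteriaConfig, optional
    zero_cell : {"haldane", "none"}
        Zero-cell policy; with ``"none"`` a zero-cell PT gets NaN statistics
        and can never be flagged.

    Examples
    --------
    >>> model = DisproportionalityAnalysis(target_pts, background_pts, soc_map)
    >>> res = model.fit()
    >>> res.signals           # flagged subset, ranked
    >>> print(res.summary())
    """

    def __init__(self, target_pts, background_pts, meddra_map: MeddraMap | None = None,
                 criteria: CriteriaConfig | None = None, zero_cell: str = "haldane"):
        if zero_cell not in ("haldane", "none"):
            raise ValueError("zero_cell must be 'haldane' or 'none'")
        self.target_pts = dict(target_pts)
        self.background_pts = dict(background_pts)
        overlap = set(self.target_pts) & set(self.background_pts)
        if overlap:
            raise ValueError(f"target and background share {len(overlap)} report ids")
        self.meddra_map = meddra_map
        self.criteria = criteria or CriteriaConfig()
        self.zero_cell = zero_cell

    @classmethod
    def from_caseset(cls, caseset, background_pts, meddra_map=None, **kw):
        return cls(caseset.pt_sets(), background_pts, meddra_map=meddra_map, **kw)

    def fit(self) -> "DisproportionalityResults":
        n_target = len(self.target_pts)
        n_bg = len(self.background_pts)
        a_counts = Counter()
        for s in self.target_pts.values():
            a_counts.update(set(s))
        c_counts = Counter()
        for s in self.background_pts.values():
            c_counts.update(set(s))

        pts = sorted(a_counts)
        if not pts:
            return DisproportionalityResults(self, _empty_results_frame())

        a = np.array([a_counts[p] for p in pts], dtype=float)
        c = np.array([c_counts.get(p, 0) for p in pts], dtype=float)
        b = n_target - a
        d = n_bg - c
        frame = _statistics_frame(pts, a, b, c, d, self.zero_cell)
        if self.meddra_map is not None:
            frame["soc"] = [self.meddra_map.lookup(p) for p in pts]
        else:
            frame["soc"] = MeddraMap.UNMAPPED
        frame = _apply_criteria(frame, self.criteria)
        frame = _rank(frame)
        return DisproportionalityResults(self, frame)


def _statistics_frame(pts, a, b, c, d, zero_cell: str) -> pd.DataFrame:
    a_raw, b_raw, c_raw, d_raw = (arr.copy() for arr in (a, b, c, d))
    zero = np.minimum(np.minimum(a, b), np.minimum(c, d)) <= 0
    if zero_cell == "haldane":
        a = a + np.where(zero, 0.5, 0.0)
        b = b + np.where(zero, 0.5, 0.0)
        c = c + np.where(zero, 0.5, 0.0)
        d = d + np.where(zero, 0.5, 0.0)
        defined = np.minimum(np.minimum(a, b), np.minimum(c, d)) > 0
    else:
        defined = ~zero
    with np.errstate(divide="ignore", invalid="ignore"):
        n = a + b + c + d
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror_ = (a * d) / (b * c)
        prr_ = (a / (a + b)) / (c / (c + d))
        chi2_ = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        ratio = a * n / ((a + c) * (a + b))   # observed / expected
        ic_ = np.log2(ratio)
        v_ic = _LN2_SQ_INV * (1 / a - 1 / (a + b) - 1 / (a + c) + 1 / n)
        ic025_ = ic_ - 2.0 * np.sqrt(np.maximum(v_ic, 0.0))
        out = pd.DataFrame({
            "pt": pts,
            "a": a_raw.astype(int),
            "b": b_raw.astype(int),
            "c": c_raw.astype(int),
            "d": d_raw.astype(int),
            "ror": ror_,
            "ror_lo95": np.exp(np.log(ror_) - 1.96 * se),
            "ror_hi95": np.exp(np.log(ror_) + 1.96 * se),
            "prr": prr_,
            "chi2": chi2_,
            "ic": ic_,
            "ic025": ic025_,
            "ebgm": ratio,
            "ebgm05": np.exp(np.log(ratio) - 1.96 * se),
            "corrected": zero if zero_cell == "haldane" else np.zeros_like(zero),
        })
    stat_cols = ["ror", "ror_lo95", "ror_hi95", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"]
    out.loc[~defined, stat_cols] = np.nan
    return out


def _apply_criteria(frame: pd.DataFrame, c: CriteriaConfig) -> pd.DataFrame:
    f = frame
    f = f.copy()
    f["pass_ror"] = (f["ror_lo95"] > c.ror_lo_gt) & (f["a"] >= c.min_n)
    f["pass_prr"] = (f["prr"] >= c.prr_min) & (f["chi2"] >= c.chi2_min) & (f["a"] >= c.min_n)
    f["pass_bcpnn"] = f["ic025"] > c.ic025_gt
    f["pass_ebgm"] = f["ebgm05"] > c.ebgm05_gt
    for col in ("pass_ror", "pass_prr", "pass_bcpnn", "pass_ebgm"):
        f[col] = f[col].fillna(False).astype(bool)
    f["is_signal"] = f["pass_ror"] & f["pass_prr"] & f["pass_bcpnn"] & f["pass_ebgm"]
    return f


def _rank(frame: pd.DataFrame) -> pd.DataFrame:
    # deterministic: by descending case count, then descending ROR, then PT
    f = frame.sort_values(["a", "ror", "pt"], ascending=[False, False, True],
                          kind="mergesort", na_position="last")
    return f.reset_index(drop=True)


def _empty_results_frame() -> pd.DataFrame:
    cols = ["pt", "a", "b", "c", "d", "ror", "ror_lo95", "ror_hi95", "prr", "chi2",
            "ic", "ic025", "ebgm", "ebgm05", "corrected", "soc",
            "pass_ror", "pass_prr", "pass_bcpnn", "pass_ebgm", "is_signal"]
    return pd.DataFrame(columns=cols)


class DisproportionalityResults:
    """Fitted per-PT statistics, flags and rankings.

    ``frame`` holds one row per PT (ranked by case count, ROR, PT);
    ``signals`` is the subset passing all four criteria jointly.
    """

    def __init__(self, model: DisproportionalityAnalysis, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def signals(self) -> pd.DataFrame:
        return self.frame[self.frame["is_signal"]].reset_index(drop=True)

    def top_by_frequency(self, k: int = 20) -> pd.DataFrame:
        return self.signals.head(k)

    def top_by_strength(self, k: int = 20) -> pd.DataFrame:
        s = self.signals.sort_values(["ror", "a", "pt"], ascending=[False, False, True],
                                     kind="mergesort")
        return s.head(k).reset_index(drop=True)

    def results(self) -> list[SignalResult]:
        """Rows as :class:`SignalResult` records (the frame is the fast path)."""
        fields = [f for f in SignalResult.__dataclass_fields__]
        return [SignalResult(**{k: row[k] for k in fields}) for _, row in self.frame.iterrows()]

    def summary(self) -> str:
        n_pt = len(self.frame)
        sig = self.signals
        lines = [
            "Disproportionality screen (ROR / PRR / BCPNN-IC / EBGM)",
            f"  target reports:     {len(self.model.target_pts)}",
            f"  background reports: {len(self.model.background_pts)}",
            f"  distinct PTs:       {n_pt}",
            f"  joint signals:      {len(sig)}",
            "",
            "  top signals by case count:",
        ]
        for _, r in sig.head(10).iterrows():
            lines.append(
                f"    {r['pt']:<32s} a={int(r['a']):>5d}  ROR {r['ror']:.2f} "
                f"({r['ror_lo95']:.2f}-{r['ror_hi95']:.2f})  chi2 {r['chi2']:.1f}  "
                f"IC025 {r['ic025']:.2f}  EBGM05 {r['ebgm05']:.2f}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (f"<DisproportionalityResults: {len(self.frame)} PTs, "
                f"{int(self.frame['is_signal'].sum())} signals>")


def detect_signals(caseset, background_pts, meddra_map: MeddraMap | None = None,
                   criteria: CriteriaConfig | None = None) -> DisproportionalityResults:
    """One-call wrapper: screen every PT of a case set against a background."""
    model = DisproportionalityAnalysis.from_caseset(
        caseset, background_pts, meddra_map=meddra_map, criteria=criteria)
    return model.fit()


def soc_aggregate(pt_sets, meddra_map: MeddraMap) -> pd.DataFrame:
    """System-organ-class counts of adverse events for the target drug.

    Counts report-PT pairs per SOC (a report with three PTs in one SOC
    contributes three) with proportions of the grand total of pairs; a
    unique-report counter per SOC is provided alongside.
    """
    sets = pt_sets.values() if hasattr(pt_sets, "values") else pt_sets
    pair_counts: Counter = Counter()
    report_counts: Counter = Counter()
    for s in sets:
        socs = [meddra_map.lookup(p) for p in s]
        pair_counts.update(socs)
        report_counts.update(set(socs))
    total = sum(pair_counts.values())
    rows = [{"soc": soc, "n_pt_reports": cnt,
             "proportion_pct": 100.0 * cnt / total if total else math.nan,
             "n_reports": report_counts[soc]}
            for soc, cnt in pair_counts.items()]
    out = pd.DataFrame(rows).sort_values(["n_pt_reports", "soc"], ascending=[False, True],
                                         kind="mergesort").reset_index(drop=True)
    return out
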