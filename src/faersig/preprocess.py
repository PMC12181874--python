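"""Deduplication, target-drug selection, and case-level assembly.

Spontaneous reporting systems receive several versions of the same case over
time.  The FDA-recommended rule keeps, per CASEID, the report version with
the latest FDA receipt date, breaking ties by the largest PRIMARYID.  After
deduplication, reports are restricted to a receipt-date window and to those
naming the target drug as primary suspect (PS), and all tables are joined
into a single case-level view (:class:`CaseSet`) from which every downstream
statistic is computed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import normalize_pt

__all__ = ["CaseSet", "deduplicate", "match_target_drug", "build_caseset"]


@dataclass
class CaseSet:
    """Deduplicated, joined case-level dataset for the target drug.

    Attributes
    ----------
    demo : DataFrame
        One row per surviving report (demo schema columns).
    pts : dict[str, frozenset[str]]
        primaryid -> set of normalized PTs (a PT repeated within a report
        counts once).
    outcomes : dict[str, frozenset[str]]
        primaryid -> set of outcome codes.
    target_drug_seqs : dict[str, list[str]]
        primaryid -> drug_seq values of the target-drug PS rows.
    therapy_starts : DataFrame
        Therapy start dates for those rows (primaryid, dsg_drug_seq,
        start_dt, start_dt_prec).
    provenance : list[tuple[str, int]]
        (stage, surviving report count) recorded at every filter stage.
    """

    demo: pd.DataFrame
    pts: dict[str, frozenset]
    outcomes: dict[str, frozenset]
    target_drug_seqs: dict[str, list]
    therapy_starts: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def primaryids(self) -> list[str]:
        return list(self.demo["primaryid"])

    def pt_sets(self) -> dict[str, frozenset]:
        return self.pts

    def subset(self, primaryids) -> "CaseSet":
        """Restrict to the given report ids (used by subgroup runs)."""
        keep = set(primaryids)
        demo = self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True)
        ther = self.therapy_starts[self.therapy_starts["primaryid"].isin(keep)]
        return CaseSet(
            demo=demo,
            pts={k: v for k, v in self.pts.items() if k in keep},
            outcomes={k: v for k, v in self.outcomes.items() if k in keep},
            target_drug_seqs={k: v for k, v in self.target_drug_seqs.items() if k in keep},
            therapy_starts=ther.reset_index(drop=True),
            provenance=list(self.provenance) + [("subset", len(demo))],
        )


def _numeric_primaryid(series: pd.Series) -> pd.Series:
    as_num = pd.to_numeric(series, errors="coerce")
    if as_num.isna().any():
        warnings.warn("non-numeric primaryid values; falling back to lexicographic order")
        # zero-pad so lexicographic order agrees with numeric order where possible
        width = series.astype(str).str.len().max()
        return series.astype(str).str.zfill(int(width))
    return as_num


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one report per case: latest fda_dt, then largest primaryid.

    Idempotent; invariant under input row order.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_pid_key"] = _numeric_primaryid(work["primaryid"])
    work = work.sort_values(["caseid", "fda_dt", "_pid_key"], kind="mergesort")
    survivors = work.groupby("caseid", sort=True).tail(1)
    return survivors.drop(columns="_pid_key").reset_index(drop=True)


def match_target_drug(drug: pd.DataFrame, patterns, role: str = "PS") -> set:
    """primaryids whose DRUG rows match any name pattern with the given role.

    Matching is case-insensitive substring against both the verbatim drug
    name and the active-ingredient string — FAERS drug names are free text
    with dose suffixes, so exact matching would miss most rows.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    if drug.empty:
        return set()
    pat = "|".join(re.escape(p) for p in patterns)
    in_role = drug["role_cod"] == role.upper()
    name_hit = drug["drugname"].astype(str).str.contains(pat, case=False, regex=True)
    ai_hit = drug["prod_ai"].astype(str).str.contains(pat, case=False, regex=True)
    return set(drug.loc[in_role & (name_hit | ai_hit), "primaryid"])


def _match_rows(drug: pd.DataFrame, patterns) -> pd.Series:
    pat = "|".join(re.escape(p) for p in patterns)
    return (drug["drugname"].astype(str).str.contains(pat, case=False, regex=True)
            | drug["prod_ai"].astype(str).str.contains(pat, case=False, regex=True))


def build_caseset(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    outc: pd.DataFrame,
    ther: pd.DataFrame,
    patterns,
    window=None,
    role: str = "PS",
    strict_monotherapy: bool = False,
) -> CaseSet:
    """Assemble the case-level dataset for the target drug.

    Parameters
    ----------
    demo : DataFrame
        Already deduplicated demographics (see :func:`deduplicate`).
    patterns : list of str
        Target-drug name keywords (case-insensitive substrings).
    window : (start, end) timestamps or None
        Inclusive FDA receipt-date window; the receipt date defines the
        window because quarterly files are organized by receipt.
    strict_monotherapy : bool
        Default reading of "monotherapy": the target drug is the only
        *primary suspect* drug in the report.  With ``strict_monotherapy``
        reports carrying any secondary-suspect (SS) drug are excluded too.

    Filter stages are monotone (each can only shrink the report set) and
    every stage count is recorded in ``provenance``.
    """
    provenance: list[tuple[str, int]] = [("deduplicated reports", len(demo))]
    work = demo

    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        mask = (work["fda_dt"] >= start) & (work["fda_dt"] <= end)
        work = work[mask]
        provenance.append(("within receipt-date window", len(work)))

    surviving = set(work["primaryid"])
    drug_live = drug[drug["primaryid"].isin(surviving)]

    target_ids = match_target_drug(drug_live, patterns, role=role)
    work = work[work["primaryid"].isin(target_ids)]
    provenance.append((f"target drug with role {role.upper()}", len(work)))

    # monotherapy: the target is the only PS drug in the report
    drug_live = drug_live[drug_live["primaryid"].isin(set(work["primaryid"]))]
    is_target = _match_rows(drug_live, patterns)
    other_ps = set(drug_live.loc[(drug_live["role_cod"] == "PS") & ~is_target, "primaryid"])
    work = work[~work["primaryid"].isin(other_ps)]
    provenance.append(("target is sole PS drug", len(work)))
    if strict_monotherapy:
        has_ss = set(drug_live.loc[drug_live["role_cod"] == "SS", "primaryid"])
        work = work[~work["primaryid"].isin(has_ss)]
        provenance.append(("no secondary-suspect drugs", len(work)))

    surviving = set(work["primaryid"])

    # REAC rows whose primaryid is absent from DEMO are orphans, not errors
    reac_known = reac[reac["primaryid"].isin(set(demo["primaryid"]))]
    n_orphans = len(reac) - len(reac_known)
    reac_live = reac_known[reac_known["primaryid"].isin(surviving)].copy()
    reac_live["pt"] = reac_live["pt"].map(normalize_pt)
    pts = {pid: frozenset(group) for pid, group in reac_live.groupby("primaryid")["pt"]}

    work = work[work["primaryid"].isin(pts.keys())]
    provenance.append(("at least one reaction PT", len(work)))
    if n_orphans:
        provenance.append(("orphan REAC rows excluded", n_orphans))
    surviving = set(work["primaryid"])
    pts = {k: v for k, v in pts.items() if k in surviving}

    outc_live = outc[outc["primaryid"].isin(surviving)]
    outcomes = {pid: frozenset(g) for pid, g in outc_live.groupby("primaryid")["outc_cod"]}

    tgt_rows = drug_live[(drug_live["role_cod"] == role.upper())
                         & _match_rows(drug_live, patterns)
                         & drug_live["primaryid"].isin(surviving)]
    target_seqs: dict[str, list] = {}
    for pid, g in tgt_rows.groupby("primaryid")["drug_seq"]:
        target_seqs[pid] = sorted(set(g))

    ther_live = ther[ther["primaryid"].isin(surviving)].reset_index(drop=True)

    return CaseSet(
        demo=work.sort_values("primaryid", kind="mergesort").reset_index(drop=True),
        pts=pts,
        outcomes=outcomes,
        target_drug_seqs=target_seqs,
        therapy_starts=ther_live,
        provenance=provenance,
    )


def background_pt_sets(demo: pd.DataFrame, reac: pd.DataFrame, target_ids) -> dict:
    """PT sets for all deduplicated reports *not* in the target set.

    These are the comparator ("all other drugs") reports of the 2x2 tables.
    """
    target = set(target_ids)
    keep = set(demo["primaryid"]) - target
    rows = reac[reac["primaryid"].isin(keep)].copy()
    rows["pt"] = rows["pt"].map(normalize_pt)
    return {pid: frozenset(g) for pid, g in rows.groupby("primaryid")["pt"]}
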