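"""Synthetic FAERS-like data with known ground truth.

Generates a spontaneous-reporting corpus — cases with duplicate report
versions, primary-suspect drug assignments, MedDRA-like PT vocabularies with
planted drug-PT associations at configurable relative risks, Weibull onset
delays, partial dates, and demographic structure — so that every pipeline
stage (parsing, deduplication, case assembly, disproportionality screening,
onset analysis) can be tested offline against a manifest of planted truth.

Planting is report-level: a planted relative risk rho means a target-drug
report mentions the PT with probability ``min(rho * p_bg, cap)`` where
``p_bg`` is the background per-report mention probability — matching the
report-level counting of the 2x2 tables downstream.

Randomness uses the Philox counter-based generator with independent
substreams per concern (case structure, PT draws, demographics, dates,
onsets, outcomes, duplicates), spawned from the single config seed, so the
same seed always yields byte-identical output files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "plant_report",
           "pt_name", "drug_name"]

TARGET_DRUG_NAMES = ["PALYNZIQ", "PALYNZIQ 20MG SOLUTION", "PEGVALIASE-PQPZ"]
TARGET_DRUG_AI = "PEGVALIASE-PQPZ"
_COUNTRY_CODES = ["US", "DE", "IT", "GB", "JP", "AR", "KW", "RU"]


def pt_name(j: int) -> str:
    return f"Event Term {j + 1:04d}"


def drug_name(k: int) -> str:
    return f"DRUG_{k:03d}"


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator.

    Defaults emulate the structure of a FAERS slice at desk scale: ~10% of
    reports name the target drug as primary suspect (so the default
    ``n_cases`` yields a target corpus in the thousands, the scale of a
    typical single-drug pharmacovigilance study), a Zipf-weighted PT
    vocabulary, three planted associations at relative risks 2/5/10, ~5%
    duplicate cases, early-failure Weibull onsets with median ~15 days, and
    roughly half of onset dates unusable — mirroring how often spontaneous
    reports omit therapy dates.
    """

    n_cases: int = 5_000
    seed: int = 0
    duplicate_rate: float = 0.05
    drug_vocab_size: int = 20
    pt_vocab_size: int = 100
    target_drug_share: float = 0.10
    #: (pt index or name, relative risk); indices are into the PT vocabulary
    planted_signals: list = field(default_factory=lambda: [(20, 2.0), (30, 5.0), (40, 10.0)])
    mean_pts_per_report: float = 3.0
    pt_prob_cap: float = 0.9
    #: extra non-target primary-suspect drug on a target case (breaks the
    #: sole-PS monotherapy rule for that report)
    extra_ps_rate: float = 0.02
    concomitant_rate: float = 0.30
    # onset model
    onset_shape: float = 0.6
    onset_scale: float = 27.0
    onset_scale_by_sex: dict | None = None
    missing_onset_rate: float = 0.50
    event_month_precision_rate: float = 0.06
    event_year_precision_rate: float = 0.02
    # demographics
    sex_probs: dict = field(default_factory=lambda: {"F": 0.41, "M": 0.28, "UNK": 0.31})
    age_missing_rate: float = 0.58
    occp_probs: dict = field(default_factory=lambda: {
        "CN": 0.830, "": 0.113, "MD": 0.039, "PH": 0.010, "OT": 0.008})
    country_probs: dict = field(default_factory=lambda: {
        "US": 0.975, "DE": 0.015, "IT": 0.004, "GB": 0.002, "JP": 0.002, "AR": 0.002})
    outcome_probs: dict = field(default_factory=lambda: {
        "DE": 0.0012, "LT": 0.008, "HO": 0.030, "DS": 0.0004,
        "CA": 0.0002, "RI": 0.0005, "OT": 0.112})
    window: tuple = ("2018-07-01", "2023-06-30")
    n_soc: int = 10

    def validate(self) -> None:
        def check_prob(name, v):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"SyntheticConfig.{name} must be in [0, 1], got {v}")

        if self.n_cases <= 0:
            raise ValueError("SyntheticConfig.n_cases must be positive")
        if self.drug_vocab_size < 2:
            raise ValueError("SyntheticConfig.drug_vocab_size must be >= 2")
        if self.pt_vocab_size < 1:
            raise ValueError("SyntheticConfig.pt_vocab_size must be >= 1")
        for name in ("duplicate_rate", "target_drug_share", "missing_onset_rate",
                     "age_missing_rate", "extra_ps_rate", "concomitant_rate",
                     "event_month_precision_rate", "event_year_precision_rate",
                     "pt_prob_cap"):
            check_prob(name, getattr(self, name))
        for name in ("sex_probs", "occp_probs", "country_probs", "outcome_probs"):
            d = getattr(self, name)
            for k, v in d.items():
                check_prob(f"{name}[{k!r}]", v)
        for name in ("sex_probs", "occp_probs", "country_probs"):
            s = sum(getattr(self, name).values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"SyntheticConfig.{name} must sum to 1, got {s}")
        for pt, rho in self.planted_signals:
            if rho < 0:
                raise ValueError(f"SyntheticConfig.planted_signals: rho for {pt!r} must be >= 0")
        if self.onset_shape <= 0 or self.onset_scale <= 0:
            raise ValueError("SyntheticConfig.onset_shape/onset_scale must be positive")
        start, end = (pd.Timestamp(t) for t in self.window)
        if start > end:
            raise ValueError("SyntheticConfig.window start must be <= end")

    # --- derived quantities -------------------------------------------------

    def pt_weights(self) -> np.ndarray:
        """Zipf-like background PT weights (rank j gets weight 1/(j+1))."""
        w = 1.0 / np.arange(1, self.pt_vocab_size + 1)
        return w / w.sum()

    def background_pt_probs(self) -> np.ndarray:
        """Per-report mention probability of each PT for background reports."""
        return np.minimum(self.mean_pts_per_report * self.pt_weights(), self.pt_prob_cap)

    def planted_indices(self) -> list[tuple[int, float]]:
        names = [pt_name(j) for j in range(self.pt_vocab_size)]
        out = []
        for pt, rho in self.planted_signals:
            j = pt if isinstance(pt, int) else names.index(pt)
            if not 0 <= j < self.pt_vocab_size:
                raise ValueError(f"planted PT index {j} outside vocabulary")
            out.append((j, float(rho)))
        return out

    def target_pt_probs(self) -> tuple[np.ndarray, list[dict]]:
        """Target-report PT probabilities plus the planted-truth records."""
        p = self.background_pt_probs().copy()
        planted = []
        for j, rho in self.planted_indices():
            raw = rho * p[j]
            capped = raw > self.pt_prob_cap
            if capped:
                warnings.warn(f"planted probability for {pt_name(j)} capped at {self.pt_prob_cap}")
            planted.append({"pt": pt_name(j), "index": j, "rho": rho,
                            "p_background": float(p[j]),
                            "p_target": float(min(raw, self.pt_prob_cap)),
                            "capped": bool(capped)})
            p[j] = min(raw, self.pt_prob_cap)
        return p, planted


@dataclass
class SyntheticDataset:
    """Generated tables (parsed schema, as :func:`faersig.io.read_table` returns)
    plus the PT->SOC toy map and the ground-truth manifest."""

    config: SyntheticConfig
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    meddra: dict
    manifest: dict

    def write(self, outdir) -> dict:
        """Write FAERS-dialect ($-delimited) files, the PT->SOC map and the
        manifest; returns the paths.  Same config + seed => byte-identical."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind, formatter in (("demo", _format_demo), ("drug", _format_drug),
                                ("reac", _format_reac), ("outc", _format_outc),
                                ("ther", _format_ther), ("indi", _format_indi)):
            path = outdir / f"{kind.upper()}.txt"
            raw = formatter(getattr(self, kind))
            raw.to_csv(path, sep="$", index=False, lineterminator="\n")
            paths[kind] = path
        map_path = outdir / "meddra_map.csv"
        with open(map_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("PT,SOC\n")
            for pt, soc in sorted(self.meddra.items()):
                fh.write(f"{pt},{soc}\n")
        paths["meddra"] = map_path
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = manifest_path
        return paths


def _date_str(ts, prec) -> str:
    if ts is None or pd.isna(ts):
        return ""
    if prec == "day":
        return f"{ts.year:04d}{ts.month:02d}{ts.day:02d}"
    if prec == "month":
        return f"{ts.year:04d}{ts.month:02d}"
    return f"{ts.year:04d}"


def _format_demo(demo: pd.DataFrame) -> pd.DataFrame:
    from .io import _COUNTRY_NAMES  # reverse lookup for writing codes
    rev = {v: k for k, v in reversed(list(_COUNTRY_NAMES.items()))}
    return pd.DataFrame({
        "PRIMARYID": demo["primaryid"],
        "CASEID": demo["caseid"],
        "FDA_DT": [_date_str(t, p) for t, p in zip(demo["fda_dt"], demo["fda_dt_prec"])],
        "EVENT_DT": [_date_str(t, p) for t, p in zip(demo["event_dt"], demo["event_dt_prec"])],
        "SEX": demo["sex"].map(lambda s: s if s in ("F", "M") else ""),
        "AGE": demo["age_years"].map(lambda a: "" if pd.isna(a) else f"{a:g}"),
        "AGE_COD": demo["age_years"].map(lambda a: "" if pd.isna(a) else "YR"),
        "OCCP_COD": demo["occp_cod"].fillna(""),
        "REPORTER_COUNTRY": demo["reporter_country"].map(lambda c: rev.get(c, c if c != "Not Specified" else "")),
    })


def _format_drug(drug: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "PRIMARYID": drug["primaryid"], "DRUG_SEQ": drug["drug_seq"],
        "ROLE_COD": drug["role_cod"], "DRUGNAME": drug["drugname"],
        "PROD_AI": drug["prod_ai"],
    })


def _format_reac(reac: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"PRIMARYID": reac["primaryid"], "PT": reac["pt"]})


def _format_outc(outc: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"PRIMARYID": outc["primaryid"], "OUTC_COD": outc["outc_cod"]})


def _format_ther(ther: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "PRIMARYID": ther["primaryid"], "DSG_DRUG_SEQ": ther["dsg_drug_seq"],
        "START_DT": [_date_str(t, p) for t, p in zip(ther["start_dt"], ther["start_dt_prec"])],
    })


def _format_indi(indi: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "PRIMARYID": indi["primaryid"], "INDI_DRUG_SEQ": indi["indi_drug_seq"],
        "INDI_PT": indi["indi_pt"],
    })


def _choice(rng, options, probs, size):
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(options, dtype=object), size=size, p=p / p.sum())


def generate(config: SyntheticConfig, outdir=None) -> SyntheticDataset:
    """Generate a full synthetic corpus; optionally write it to ``outdir``."""
    config.validate()
    cfg = config
    n = cfg.n_cases
    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rng_case, rng_pt, rng_demo, rng_date, rng_onset, rng_outc, rng_dup = (
        np.random.Generator(np.random.Philox(s)) for s in streams)

    # --- case-level structure ---------------------------------------------
    is_target = rng_case.random(n) < cfg.target_drug_share
    other_drug = 1 + rng_case.integers(0, cfg.drug_vocab_size - 1, size=n)
    drug_idx = np.where(is_target, 0, other_drug)
    extra_ps = rng_case.random(n) < cfg.extra_ps_rate
    concom = rng_case.random(n) < cfg.concomitant_rate
    concom_drug = 1 + rng_case.integers(0, cfg.drug_vocab_size - 1, size=n)
    extra_ps_drug = 1 + rng_case.integers(0, cfg.drug_vocab_size - 1, size=n)

    # --- PT inclusion matrix ------------------------------------------------
    p_bg = cfg.background_pt_probs()
    p_target, planted = cfg.target_pt_probs()
    probs = np.where(is_target[:, None], p_target[None, :], p_bg[None, :])
    mentions = rng_pt.random((n, cfg.pt_vocab_size)) < probs
    empty = ~mentions.any(axis=1)
    if empty.any():
        fallback = rng_pt.choice(cfg.pt_vocab_size, size=int(empty.sum()), p=cfg.pt_weights())
        mentions[np.nonzero(empty)[0], fallback] = True

    # --- demographics -------------------------------------------------------
    sex = _choice(rng_demo, list(cfg.sex_probs), list(cfg.sex_probs.values()), n)
    age = np.round(rng_demo.normal(31.0, 12.0, size=n).clip(1.0, 90.0), 0)
    age[rng_demo.random(n) < cfg.age_missing_rate] = np.nan
    occp = _choice(rng_demo, list(cfg.occp_probs), list(cfg.occp_probs.values()), n)
    country = _choice(rng_demo, list(cfg.country_probs), list(cfg.country_probs.values()), n)

    # --- dates and onsets ---------------------------------------------------
    win_start, win_end = (pd.Timestamp(t) for t in cfg.window)
    span = (win_end - win_start).days
    start_offset = rng_date.integers(0, span + 1, size=n)
    scale = np.full(n, float(cfg.onset_scale))
    if cfg.onset_scale_by_sex:
        for s, val in cfg.onset_scale_by_sex.items():
            scale[sex == s] = float(val)
    onset_days = np.floor(rng_onset.weibull(cfg.onset_shape, size=n) * scale).astype(int)
    report_delay = rng_date.integers(0, 46, size=n)
    ther_missing = rng_date.random(n) < cfg.missing_onset_rate
    u_prec = rng_date.random(n)
    event_prec = np.where(u_prec < cfg.event_year_precision_rate, "year",
                          np.where(u_prec < cfg.event_year_precision_rate
                                   + cfg.event_month_precision_rate, "month", "day"))

    # --- outcomes -----------------------------------------------------------
    out_codes = list(cfg.outcome_probs)
    out_draws = rng_outc.random((n, len(out_codes))) < np.array(list(cfg.outcome_probs.values()))

    # --- duplicate report versions -----------------------------------------
    has_dup = rng_dup.random(n) < cfg.duplicate_rate
    extra_versions = np.where(has_dup, 1 + (rng_dup.random(n) < 0.3).astype(int), 0)

    # --- assemble report-level rows ----------------------------------------
    n_versions = 1 + extra_versions
    case_of_report = np.repeat(np.arange(n), n_versions)
    version = np.concatenate([np.arange(k) for k in n_versions])
    caseids = (1_000_001 + case_of_report).astype(str)
    primaryids = ((1_000_001 + case_of_report) * 10 + version).astype(str)
    # primaryid of each case's version-v report, for expanding case-level rows
    pid_of = (1_000_001 + np.arange(n)) * 10

    start_np = (win_start.to_datetime64()
                + start_offset.astype("timedelta64[D]"))
    event_np = start_np + onset_days.astype("timedelta64[D]")
    fda_np = np.minimum(event_np + report_delay.astype("timedelta64[D]"),
                        win_end.to_datetime64())
    fda_report = fda_np[case_of_report] + (version * 7).astype("timedelta64[D]")

    event_ser = pd.Series(event_np)
    m = event_prec == "month"
    y = event_prec == "year"
    event_ser[m] = event_ser[m].dt.to_period("M").dt.to_timestamp()
    event_ser[y] = event_ser[y].dt.to_period("Y").dt.to_timestamp()
    event_floored = event_ser.to_numpy()

    demo = pd.DataFrame({
        "primaryid": primaryids,
        "caseid": caseids,
        "fda_dt": pd.DatetimeIndex(fda_report).as_unit("ns"),
        "fda_dt_prec": "day",
        "event_dt": pd.DatetimeIndex(event_floored[case_of_report]).as_unit("ns"),
        "event_dt_prec": event_prec[case_of_report],
        "sex": sex[case_of_report],
        "age_years": age[case_of_report],
        "occp_cod": pd.Series(occp[case_of_report]).replace("", None),
        "reporter_country": pd.Series(country[case_of_report]).map(_display_country),
    })

    def expand(case_idx: np.ndarray, columns: dict) -> pd.DataFrame:
        """Replicate case-level rows once per report version of each case."""
        frames = []
        vmax = int(n_versions.max())
        for v in range(vmax):
            live = n_versions[case_idx] > v
            cols = {"primaryid": (pid_of[case_idx[live]] + v).astype(str)}
            for name, arr in columns.items():
                cols[name] = np.asarray(arr, dtype=object)[live] if not np.issubdtype(
                    np.asarray(arr).dtype, np.datetime64) else np.asarray(arr)[live]
            frames.append(pd.DataFrame(cols))
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    drug_names = _drug_name_table(cfg)
    # primary-suspect row per case (+ optional extra PS / concomitant rows)
    variant = np.arange(n) % len(TARGET_DRUG_NAMES)
    ps_name = np.array([TARGET_DRUG_NAMES[variant[i]] if drug_idx[i] == 0
                        else drug_names[drug_idx[i]][0] for i in range(n)], dtype=object)
    ps_ai = np.array([TARGET_DRUG_AI if drug_idx[i] == 0
                      else drug_names[drug_idx[i]][1] for i in range(n)], dtype=object)
    parts = [expand(np.arange(n), {"drug_seq": np.full(n, "1", dtype=object),
                                   "role_cod": np.full(n, "PS", dtype=object),
                                   "drugname": ps_name, "prod_ai": ps_ai})]
    idx2 = np.nonzero(extra_ps)[0]
    if len(idx2):
        parts.append(expand(idx2, {
            "drug_seq": np.full(len(idx2), "2", dtype=object),
            "role_cod": np.full(len(idx2), "PS", dtype=object),
            "drugname": np.array([drug_names[k][0] for k in extra_ps_drug[idx2]], dtype=object),
            "prod_ai": np.array([drug_names[k][1] for k in extra_ps_drug[idx2]], dtype=object)}))
    idx3 = np.nonzero(concom)[0]
    if len(idx3):
        seq3 = np.where(extra_ps[idx3], "3", "2").astype(object)
        parts.append(expand(idx3, {
            "drug_seq": seq3,
            "role_cod": np.full(len(idx3), "C", dtype=object),
            "drugname": np.array([drug_names[k][0] for k in concom_drug[idx3]], dtype=object),
            "prod_ai": np.array([drug_names[k][1] for k in concom_drug[idx3]], dtype=object)}))
    drug_rows = (pd.concat(parts, ignore_index=True)
                 .sort_values(["primaryid", "drug_seq"], kind="mergesort")
                 .reset_index(drop=True))

    pair_case, pair_pt = np.nonzero(mentions)
    pt_names = np.array([pt_name(j) for j in range(cfg.pt_vocab_size)], dtype=object)
    reac_rows = expand(pair_case, {"pt": pt_names[pair_pt]})

    oc_case, oc_j = np.nonzero(out_draws)
    code_arr = np.array(out_codes, dtype=object)
    outc_rows = expand(oc_case, {"outc_cod": code_arr[oc_j]})

    ther_rows = expand(np.arange(n), {
        "dsg_drug_seq": np.full(n, "1", dtype=object),
        "start_dt": np.where(ther_missing, np.datetime64("NaT"), start_np),
        "start_dt_prec": np.where(ther_missing, None, "day").astype(object)})
    ther_rows["start_dt"] = pd.DatetimeIndex(ther_rows["start_dt"]).as_unit("ns")

    indi_rows = expand(np.arange(n), {
        "indi_drug_seq": np.full(n, "1", dtype=object),
        "indi_pt": np.where(is_target, "Phenylketonuria", "Indication Unspecified").astype(object)})

    meddra = {pt_name(j): f"Body System {j % cfg.n_soc + 1:02d}"
              for j in range(cfg.pt_vocab_size)}

    survivors = {str(1_000_001 + i): str((1_000_001 + i) * 10 + extra_versions[i])
                 for i in range(n)}
    target_case_idx = np.nonzero(is_target)[0]
    manifest = {
        "n_cases": int(n),
        "n_reports": int(n_versions.sum()),
        "seed": int(cfg.seed),
        "planted": planted,
        "survivors": survivors,
        "target_caseids": [str(1_000_001 + i) for i in target_case_idx],
        "monotherapy_broken_caseids": [str(1_000_001 + i)
                                       for i in np.nonzero(is_target & extra_ps)[0]],
        "true_onset_days": {survivors[str(1_000_001 + i)]: int(onset_days[i])
                            for i in target_case_idx},
        "onset_shape": cfg.onset_shape,
        "onset_scale": cfg.onset_scale,
    }

    ds = SyntheticDataset(cfg, demo, drug_rows, reac_rows, outc_rows, ther_rows,
                          indi_rows, meddra, manifest)
    if outdir is not None:
        ds.write(outdir)
    return ds


def _display_country(code: str) -> str:
    from .io import normalize_country
    return normalize_country(code)


def _drug_name_table(cfg) -> list[tuple[str, str]]:
    # index 0 is the target drug; its free-text name variants are assigned
    # deterministically per case in generate()
    table = [(TARGET_DRUG_NAMES[0], TARGET_DRUG_AI)]
    for k in range(1, cfg.drug_vocab_size):
        table.append((drug_name(k), f"INGREDIENT_{k:03d}"))
    return table


def plant_report(case: dict, config: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Reference single-case planting semantics.

    Given a case dict with at least ``is_target`` (bool), draws the report's
    PT set: planted PTs with probability ``min(rho * p_bg, cap)`` for target
    cases and ``p_bg`` otherwise, background PTs at their background rates,
    with at least one PT guaranteed.  Returns ``{"pts": set, "capped":
    [...]}.``  The bulk generator applies exactly these probabilities
    vectorized; this function documents and tests them one case at a time.
    """
    config.validate()
    p_bg = config.background_pt_probs()
    p_target, planted = config.target_pt_probs()
    probs = p_target if case.get("is_target") else p_bg
    draw = rng.random(config.pt_vocab_size) < probs
    if not draw.any():
        draw[rng.choice(config.pt_vocab_size, p=config.pt_weights())] = True
    return {
        "pts": {pt_name(j) for j in np.nonzero(draw)[0]},
        "capped": [p["pt"] for p in planted if p["capped"]],
    }
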