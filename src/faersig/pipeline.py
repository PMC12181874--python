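"""End-to-end pipeline: read -> deduplicate -> select -> screen -> describe.

:func:`run_pipeline` wires the modules together from a :class:`RunConfig`
(usually loaded from YAML), writes every output table as CSV, and logs
per-stage report counts to a provenance file.  Outputs are deterministic for
fixed inputs and configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from . import preprocess
from .descriptives import (SubgroupSpec, characteristics_table, bin_onsets,
                           compute_onsets, weibull_fit)
from .signals import CriteriaConfig, detect_signals, soc_aggregate

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A fatal failure, carrying the name of the stage that failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    target_patterns: list = field(default_factory=lambda: ["pegvaliase", "palynziq"])
    role: str = "PS"
    window: tuple | None = ("2018-07-01", "2023-06-30")
    meddra_map: str | None = None
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    subgroups: list = field(default_factory=lambda: ["sex", "age_years", "occp_cod"])
    age_bins: str = "table3"
    strict_monotherapy: bool = False
    delimiter: str = "$"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        crit = CriteriaConfig(**raw.pop("criteria", {}))
        window = raw.pop("window", None)
        return cls(criteria=crit, window=tuple(window) if window else None, **raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["window"] = list(self.window) if self.window else None
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _read_inputs(cfg: RunConfig) -> dict:
    indir = Path(cfg.input_dir)
    if not indir.is_dir():
        raise PipelineError("faers_io", f"input directory {indir} does not exist")
    tables = {}
    for kind in ("demo", "drug", "reac", "outc", "ther"):
        matches = sorted(indir.glob(f"{kind.upper()}*.txt")) + sorted(indir.glob(f"{kind}*.txt"))
        if not matches:
            raise PipelineError("faers_io", f"no {kind.upper()}*.txt file in {indir}")
        parts = [fio.read_table(p, kind, delimiter=cfg.delimiter) for p in matches]
        tables[kind] = pd.concat([p.frame for p in parts], ignore_index=True)
        tables[f"{kind}_rejected"] = sum(p.n_rejected for p in parts)
    return tables


def run_pipeline(cfg: RunConfig, log=print) -> dict:
    """Run the whole analysis; returns the in-memory products and writes CSVs."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = _read_inputs(cfg)
    meddra = fio.read_meddra_map(cfg.meddra_map) if cfg.meddra_map else fio.MeddraMap({})

    deduped = preprocess.deduplicate(tables["demo"])
    caseset = preprocess.build_caseset(
        deduped, tables["drug"], tables["reac"], tables["outc"], tables["ther"],
        patterns=cfg.target_patterns, window=cfg.window, role=cfg.role,
        strict_monotherapy=cfg.strict_monotherapy)
    if len(caseset) == 0:
        raise PipelineError("preprocess", "no reports match the target drug in the window")

    background = preprocess.background_pt_sets(deduped, tables["reac"], caseset.primaryids)
    results = detect_signals(caseset, background, meddra_map=meddra, criteria=cfg.criteria)
    soc_tbl = soc_aggregate(caseset.pt_sets(), meddra)

    chars = characteristics_table(caseset, age_bins=cfg.age_bins)
    onsets, n_missing = compute_onsets(caseset)
    onset_tbl = bin_onsets(onsets, total_reports=len(caseset), n_missing=n_missing)
    weib = None
    if len(onsets) >= 10 and onsets["days"].nunique() > 1:
        weib = weibull_fit(onsets)

    from .descriptives import subgroup_run  # local import avoids cycle at module load
    subgroup_tables = {}
    bg_demo = deduped[~deduped["primaryid"].isin(set(caseset.primaryids))]
    for fld in cfg.subgroups:
        runs = subgroup_run(caseset, bg_demo, background, SubgroupSpec(fld),
                            meddra_map=meddra, criteria=cfg.criteria)
        rows = []
        for stratum, entry in runs.items():
            f = entry["results"].frame.copy()
            f.insert(0, "stratum", stratum)
            rows.append(f)
        subgroup_tables[fld] = (pd.concat(rows, ignore_index=True)
                                if rows else pd.DataFrame())
        subgroup_tables[f"{fld}_summary"] = pd.DataFrame([
            {"stratum": s, "n_cases": e["n_cases"], "n_onsets": e["n_onsets"],
             "onset_median": e["onset_median"], "onset_q1": e["onset_q1"],
             "onset_q3": e["onset_q3"], "onset_min": e["onset_min"],
             "onset_max": e["onset_max"]}
            for s, e in runs.items()])

    # --- write outputs ------------------------------------------------------
    fio.write_table(results.frame, outdir / "signals.csv")
    fio.write_table(soc_tbl, outdir / "soc_table.csv")
    fio.write_table(chars, outdir / "characteristics.csv")
    fio.write_table(onsets, outdir / "onsets.csv")
    fio.write_table(onset_tbl, outdir / "onset_bins.csv")
    if weib is not None:
        fio.write_table(pd.DataFrame([dataclasses.asdict(weib)]), outdir / "weibull.csv")
    for fld in cfg.subgroups:
        fio.write_table(subgroup_tables[fld], outdir / f"subgroup_{fld}.csv")
        fio.write_table(subgroup_tables[f"{fld}_summary"], outdir / f"subgroup_{fld}_summary.csv")
    cfg.to_yaml(outdir / "resolved_config.yaml")

    provenance_lines = [f"{stage}: {count}" for stage, count in caseset.provenance]
    for kind in ("demo", "drug", "reac", "outc", "ther"):
        provenance_lines.append(f"rejected {kind} rows: {tables[f'{kind}_rejected']}")
    (outdir / "provenance.txt").write_text("\n".join(provenance_lines) + "\n")
    for line in provenance_lines:
        log(line)

    return {"caseset": caseset, "results": results, "soc_table": soc_tbl,
            "characteristics": chars, "onsets": onsets, "onset_bins": onset_tbl,
            "weibull": weib, "subgroups": subgroup_tables}
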