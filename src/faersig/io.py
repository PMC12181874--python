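"""Reading and writing FAERS-dialect quarterly ASCII tables.

The public FAERS quarterly extracts ship as dollar-sign-delimited text with a
single header line (``DEMOyyQq.txt``, ``DRUGyyQq.txt``, ...).  This module
parses those files into pandas DataFrames with validated, typed columns, and
writes every pipeline output as RFC-4180 CSV.

Column contracts (one DataFrame "schema" per table kind):

* ``demo``: primaryid, caseid, fda_dt / fda_dt_prec, event_dt / event_dt_prec,
  sex, age_years, occp_cod, reporter_country
* ``drug``: primaryid, drug_seq, role_cod (PS/SS/C/I), drugname, prod_ai
* ``reac``: primaryid, pt
* ``outc``: primaryid, outc_cod (DE/LT/HO/DS/CA/RI/OT)
* ``ther``: primaryid, dsg_drug_seq, start_dt / start_dt_prec
* ``indi``: primaryid, indi_drug_seq, indi_pt

Dates are frequently partial in FAERS (``YYYY`` or ``YYYYMM``).  They are
parsed to a timestamp floored to the period start plus a precision tag in
{"day", "month", "year"}; any downstream computation needing day precision
must check the tag — partial dates are never silently promoted.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableReadResult",
    "MeddraMap",
    "read_table",
    "read_meddra_map",
    "write_table",
    "parse_faers_date",
    "age_to_years",
    "normalize_pt",
    "normalize_country",
    "SCHEMAS",
    "ROLE_CODES",
    "OUTCOME_CODES",
    "SchemaError",
]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Required / optional source columns per table kind (upper-case, as in FAERS).
SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "demo": {
        "required": ("PRIMARYID", "CASEID", "FDA_DT"),
        "optional": ("EVENT_DT", "SEX", "AGE", "AGE_COD", "OCCP_COD", "REPORTER_COUNTRY"),
    },
    "drug": {
        "required": ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
        "optional": ("PROD_AI",),
    },
    "reac": {"required": ("PRIMARYID", "PT"), "optional": ()},
    "outc": {"required": ("PRIMARYID", "OUTC_COD"), "optional": ()},
    "ther": {"required": ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT"), "optional": ()},
    "indi": {"required": ("PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"), "optional": ()},
}

# Small display-name table for the country codes that actually occur in this
# corpus; anything unknown passes through verbatim.
_COUNTRY_NAMES = {
    "US": "The United States",
    "USA": "The United States",
    "UNITED STATES": "The United States",
    "DE": "Germany",
    "GB": "United Kingdom",
    "UK": "United Kingdom",
    "IT": "Italy",
    "JP": "Japan",
    "AR": "Argentina",
    "KW": "Kuwait",
    "RU": "Russia",
    "FR": "France",
    "CA": "Canada",
}

_AGE_TO_YEARS = {
    "DEC": 10.0,  # decades
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
}


class SchemaError(ValueError):
    """A file does not carry the columns its table kind requires."""


def parse_faers_date(raw) -> tuple[pd.Timestamp, str | None]:
    """Parse a FAERS date field (YYYYMMDD / YYYYMM / YYYY).

    Returns ``(timestamp, precision)`` where precision is ``"day"``,
    ``"month"`` or ``"year"``; unparseable or empty input gives
    ``(NaT, None)``.  Month/year dates are floored to the period start and
    keep their precision tag so nothing downstream mistakes them for day
    precision.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return pd.NaT, None
    s = str(raw).strip()
    if s.endswith(".0"):  # pandas float round-trip of an integer column
        s = s[:-2]
    if not s.isdigit():
        return pd.NaT, None
    try:
        if len(s) == 8:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), int(s[6:8])), "day"
        if len(s) == 6:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), 1), "month"
        if len(s) == 4:
            return pd.Timestamp(int(s), 1, 1), "year"
    except ValueError:
        return pd.NaT, None
    return pd.NaT, None


def age_to_years(age, age_cod) -> float:
    """Convert a FAERS age + unit code to years; unknown unit or bad value -> NaN."""
    try:
        value = float(age)
    except (TypeError, ValueError):
        return np.nan
    if np.isnan(value) or value < 0:
        return np.nan
    code = str(age_cod).strip().upper() if age_cod is not None else "YR"
    if code in ("", "NAN", "NONE"):
        code = "YR"
    factor = _AGE_TO_YEARS.get(code)
    if factor is None:
        return np.nan
    return value * factor


def normalize_pt(pt: str) -> str:
    """Canonical PT spelling: trim, collapse internal whitespace, title case."""
    return " ".join(str(pt).split()).title()


def normalize_country(raw) -> str:
    """Map 2-letter codes to display names; unknown strings pass through."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "Not Specified"
    s = str(raw).strip()
    if not s:
        return "Not Specified"
    return _COUNTRY_NAMES.get(s.upper(), s)


@dataclass
class TableReadResult:
    """A parsed table plus its line-accounting report.

    Invariant: ``n_read + n_rejected`` equals the number of data lines in the
    source file.
    """

    kind: str
    frame: pd.DataFrame
    n_lines: int = 0
    n_read: int = 0
    n_rejected: int = 0
    rejections: Counter = field(default_factory=Counter)

    def __post_init__(self):
        assert self.n_read + self.n_rejected == self.n_lines


def _read_delimited(path: Path, delimiter: str) -> tuple[list[str], list[list[str]]]:
    # FAERS ASCII files are not UTF-8 clean; latin-1 never fails to decode.
    text = Path(path).read_text(encoding="latin-1")
    if delimiter == "$":
        lines = [ln for ln in text.splitlines() if ln != ""]
        rows = [ln.split("$") for ln in lines]
    else:
        rows = list(csv.reader(_io.StringIO(text), delimiter=delimiter))
        rows = [r for r in rows if r]
    if not rows:
        return [], []
    return [h.strip().upper() for h in rows[0]], rows[1:]


def read_table(path, kind: str, delimiter: str = "$") -> TableReadResult:
    """Read one FAERS-dialect table into a validated DataFrame.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header line.
    kind : {"demo", "drug", "reac", "outc", "ther", "indi"}
        Which schema to validate against.
    delimiter : str
        ``"$"`` for the FAERS ASCII dialect (default); ``","`` or ``"\\t"``
        are accepted for pre-converted extracts.

    Rows violating a closed vocabulary (drug role codes, outcome codes) or
    missing a required field are rejected and counted, never silently kept;
    unparseable *optional* fields become missing values.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    schema = SCHEMAS[kind]
    header, lines = _read_delimited(Path(path), delimiter)
    if not header:
        warnings.warn(f"{path}: empty file, returning empty {kind} table")
        return TableReadResult(kind, _empty_frame(kind))
    missing = [c for c in schema["required"] if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for kind {kind!r}")

    idx = {c: header.index(c) for c in header}

    def get(row: list[str], col: str) -> str | None:
        i = idx.get(col)
        if i is None or i >= len(row):
            return None
        v = row[i].strip()
        return v if v else None

    rejections: Counter = Counter()
    records: list[dict] = []
    for row in lines:
        rec = _parse_row(kind, row, get, rejections)
        if rec is not None:
            records.append(rec)
    frame = pd.DataFrame(records) if records else _empty_frame(kind)
    return TableReadResult(
        kind,
        frame,
        n_lines=len(lines),
        n_read=len(records),
        n_rejected=sum(rejections.values()),
        rejections=rejections,
    )


def _parse_row(kind, row, get, rejections):
    pid = get(row, "PRIMARYID")
    if pid is None:
        rejections["missing primaryid"] += 1
        return None
    if kind == "demo":
        caseid = get(row, "CASEID")
        fda_raw = get(row, "FDA_DT")
        if caseid is None:
            rejections["missing caseid"] += 1
            return None
        fda_dt, fda_prec = parse_faers_date(fda_raw)
        if pd.isna(fda_dt):
            rejections["unparseable fda_dt"] += 1
            return None
        event_dt, event_prec = parse_faers_date(get(row, "EVENT_DT"))
        sex = (get(row, "SEX") or "").upper()
        if sex not in ("F", "M"):
            sex = "UNK"
        return {
            "primaryid": pid,
            "caseid": caseid,
            "fda_dt": fda_dt,
            "fda_dt_prec": fda_prec,
            "event_dt": event_dt,
            "event_dt_prec": event_prec,
            "sex": sex,
            "age_years": age_to_years(get(row, "AGE"), get(row, "AGE_COD")),
            "occp_cod": (get(row, "OCCP_COD") or "").upper() or None,
            "reporter_country": normalize_country(get(row, "REPORTER_COUNTRY")),
        }
    if kind == "drug":
        role = (get(row, "ROLE_COD") or "").upper()
        if role not in ROLE_CODES:
            rejections["invalid role_cod"] += 1
            return None
        seq = get(row, "DRUG_SEQ")
        if seq is None:
            rejections["missing drug_seq"] += 1
            return None
        return {
            "primaryid": pid,
            "drug_seq": seq,
            "role_cod": role,
            "drugname": get(row, "DRUGNAME") or "",
            "prod_ai": get(row, "PROD_AI") or "",
        }
    if kind == "reac":
        pt = get(row, "PT")
        if pt is None or not normalize_pt(pt):
            rejections["empty pt"] += 1
            return None
        return {"primaryid": pid, "pt": normalize_pt(pt)}
    if kind == "outc":
        code = (get(row, "OUTC_COD") or "").upper()
        if code not in OUTCOME_CODES:
            rejections["invalid outc_cod"] += 1
            return None
        return {"primaryid": pid, "outc_cod": code}
    if kind == "ther":
        seq = get(row, "DSG_DRUG_SEQ")
        if seq is None:
            rejections["missing dsg_drug_seq"] += 1
            return None
        start_dt, start_prec = parse_faers_date(get(row, "START_DT"))
        return {
            "primaryid": pid,
            "dsg_drug_seq": seq,
            "start_dt": start_dt,
            "start_dt_prec": start_prec,
        }
    if kind == "indi":
        seq = get(row, "INDI_DRUG_SEQ")
        if seq is None:
            rejections["missing indi_drug_seq"] += 1
            return None
        return {"primaryid": pid, "indi_drug_seq": seq, "indi_pt": get(row, "INDI_PT") or ""}
    raise AssertionError(kind)


_EMPTY_COLUMNS = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "fda_dt_prec", "event_dt", "event_dt_prec",
        "sex", "age_years", "occp_cod", "reporter_country",
    ],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "start_dt_prec"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
}


def _empty_frame(kind: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_EMPTY_COLUMNS[kind])


class MeddraMap:
    """A user-supplied PT -> System Organ Class mapping.

    MedDRA itself is licensed and never bundled; users provide a two-column
    delimited file (PT, SOC).  Lookup is case/whitespace-normalized and total:
    a PT absent from the table maps to the sentinel ``"Unmapped"``.
    """

    UNMAPPED = "Unmapped"

    def __init__(self, mapping: dict[str, str]):
        self._map = {normalize_pt(k): str(v).strip() for k, v in mapping.items()}

    def lookup(self, pt: str) -> str:
        return self._map.get(normalize_pt(pt), self.UNMAPPED)

    __call__ = lookup

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def read_meddra_map(path, delimiter: str = ",") -> MeddraMap:
    """Read a PT,SOC table; duplicate PTs with conflicting SOCs are fatal."""
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: empty PT->SOC map")
        rows = [header] if len(header) >= 2 and header[0].strip().upper() not in ("PT", "PREFERRED_TERM") else []
        rows.extend(reader)
    for row in rows:
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise SchemaError(f"{path}: PT->SOC map row has fewer than 2 columns: {row}")
        pt, soc = normalize_pt(row[0]), row[1].strip()
        if pt in mapping and mapping[pt] != soc:
            raise SchemaError(f"{path}: PT {row[0]!r} mapped to conflicting SOCs "
                              f"({mapping[pt]!r} vs {soc!r})")
        mapping[pt] = soc
    return MeddraMap(mapping)


def write_table(frame: pd.DataFrame, path) -> None:
    """Write any pipeline output as RFC-4180 CSV (header always present).

    Floats are written with 12 significant digits so numeric outputs
    round-trip through :func:`pandas.read_csv` to working precision.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL,
                 float_format="%.12g", lineterminator="\n")
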