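"""Parsing and harmonisation of FAERS-dialect quarterly tables.

Covers the report-cleaning steps that precede any disproportionality
analysis: tolerant parsing of the $-delimited ASCII dialect, age-unit and
date harmonisation, the two-stage duplicate removal (most-recent version per
CASEID, then suspected re-entries matched on age/sex/country/event date),
primary-suspect drug-name selection, and PT -> system organ class mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RawTables",
    "parse_tables",
    "harmonize",
    "dedup_reports",
    "drop_field_duplicates",
    "target_primaryids",
    "select_target_reports",
    "load_pt_soc_map",
    "map_pts",
    "normalize_pt",
    "SERIOUS_OUTCOMES",
    "AGE_UNIT_TO_YEARS",
]

SERIOUS_OUTCOMES = frozenset({"DE", "LT", "HO", "DS"})

# divisor converting an age value with the given FAERS unit code to years
AGE_UNIT_TO_YEARS = {
    "DEC": 0.1, "YR": 1.0, "MON": 12.0, "WK": 52.143, "DY": 365.25, "HR": 8766.0,
}

# columns that must exist in the file (schema) ...
_MANDATORY = {
    "demo": ["PRIMARYID", "CASEID", "FDA_DT"],
    "drug": ["PRIMARYID", "ROLE_COD", "DRUGNAME"],
    "reac": ["PRIMARYID", "PT"],
    "outc": ["PRIMARYID", "OUTC_COD"],
    "ther": ["PRIMARYID", "START_DT"],
}
# ... and those whose value must be non-empty for the row to make sense;
# other fields (e.g. a therapy start date) may be legitimately missing
_REQUIRED_VALUES = {
    "demo": ["PRIMARYID", "CASEID", "FDA_DT"],
    "drug": ["PRIMARYID", "DRUGNAME"],
    "reac": ["PRIMARYID", "PT"],
    "outc": ["PRIMARYID", "OUTC_COD"],
    "ther": ["PRIMARYID"],
}

_FILES = {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt",
          "outc": "OUTC.txt", "ther": "THER.txt"}


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass
class RawTables:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    malformed: dict[str, int] = field(default_factory=dict)


def _read_dollar(path: Path, name: str) -> tuple[pd.DataFrame, int]:
    bad = [0]

    def _on_bad(line: list[str]) -> None:
        bad[0] += 1
        return None

    df = pd.read_csv(
        path, sep="$", dtype=str, keep_default_na=False, engine="python",
        on_bad_lines=_on_bad,
    )
    for col in _MANDATORY[name]:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: mandatory column {col!r} missing")
    # rows too short are NaN-padded by the reader: count and drop those whose
    # mandatory fields came out empty
    df = df.fillna("")
    short = (df[_REQUIRED_VALUES[name]] == "").any(axis=1)
    if short.any():
        bad[0] += int(short.sum())
        df = df[~short].reset_index(drop=True)
    return df, bad[0]


def parse_tables(directory: str | Path) -> RawTables:
    """Read the five FAERS-dialect files from a directory.

    Every row is either parsed or counted in the per-table ``malformed``
    tally (wrong field count, or empty mandatory field) and skipped; nothing
    is dropped silently.
    """
    directory = Path(directory)
    frames, malformed = {}, {}
    for name, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"expected table file {path}")
        frames[name], malformed[name] = _read_dollar(path, name)
        if malformed[name]:
            logger.warning("%s: skipped %d malformed row(s)", fname, malformed[name])
    return RawTables(**frames, malformed=malformed)


def parse_date_key(value: str) -> tuple[float, int]:
    """Parse a FAERS date of form YYYYMMDD, YYYYMM or YYYY.

    Returns ``(sort_key, precision_digits)`` where the key is the value
    zero-padded to 8 digits (so partial dates sort before complete dates of
    the same year-month) and precision is 4, 6 or 8; unparseable or missing
    dates give ``(nan, 0)``.
    """
    s = str(value).strip()
    if len(s) in (4, 6, 8) and s.isdigit():
        return float(int(s.ljust(8, "0"))), len(s)
    return float("nan"), 0


def _date_keys(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    s = series.astype(str).str.strip()
    digits = s.str.fullmatch(r"\d{4}|\d{6}|\d{8}")
    prec = s.str.len().where(digits, 0).fillna(0).astype(int)
    key = pd.to_numeric(s.str.ljust(8, "0").where(digits), errors="coerce")
    return key, prec


def harmonize(raw: RawTables) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Turn raw string tables into typed report, drug and reaction frames.

    Returns ``(reports, drugs, reactions)``:

    * ``reports`` — one row per PRIMARYID with caseid, fda_dt, event-date key
      and precision, sex, age_years (unit-harmonised), age_group, reporter,
      country (occurrence country, falling back to reporter country),
      outcome-code string and the ``serious`` flag (death, life-threatening,
      hospitalisation or disability).
    * ``drugs`` — drug mentions with role code, name and therapy start date.
    * ``reactions`` — one row per distinct (report, PT), PT case-normalised.
    """
    demo = raw.demo.copy()
    reports = pd.DataFrame({"primaryid": demo["PRIMARYID"].astype(str)})
    reports["caseid"] = demo["CASEID"].astype(str)
    fda_key, _ = _date_keys(demo["FDA_DT"])
    reports["fda_dt"] = fda_key
    ev = demo.get("EVENT_DT", pd.Series("", index=demo.index)).astype(str).str.strip()
    ev_key, ev_prec = _date_keys(ev)
    reports["event_dt"] = ev
    reports["event_dt_key"] = ev_key
    reports["event_dt_precision"] = ev_prec
    reports["event_date"] = pd.to_datetime(
        ev.where(ev_prec == 8), format="%Y%m%d", errors="coerce"
    )

    sex = demo.get("SEX", pd.Series("", index=demo.index)).astype(str).str.strip().str.upper()
    reports["sex"] = sex.map({"F": "female", "M": "male"}).fillna("unknown")

    age = pd.to_numeric(demo.get("AGE", pd.Series("", index=demo.index)), errors="coerce")
    cod = (
        demo.get("AGE_COD", pd.Series("", index=demo.index))
        .astype(str).str.strip().str.upper().replace("", "YR")
    )
    div = cod.map(AGE_UNIT_TO_YEARS)
    age_years = age / div
    age_years[age_years < 0] = np.nan
    reports["age_years"] = age_years
    reports["age_group"] = age_group(age_years)

    occ = demo.get("OCCP_COD", pd.Series("", index=demo.index)).astype(str).str.strip().str.upper()
    reports["reporter"] = occ.map(
        {"CN": "consumer", "PH": "pharmacist", "MD": "physician",
         "OT": "other health professional", "HP": "other health professional"}
    ).fillna("unknown")

    occr = demo.get("OCCR_COUNTRY", pd.Series("", index=demo.index)).astype(str).str.strip()
    repc = demo.get("REPORTER_COUNTRY", pd.Series("", index=demo.index)).astype(str).str.strip()
    reports["country"] = occr.where(occr != "", repc)

    outc = raw.outc
    codes = (
        outc.assign(code=outc["OUTC_COD"].astype(str).str.strip().str.upper())
        .groupby(outc["PRIMARYID"].astype(str))["code"]
        .agg(lambda s: ",".join(sorted(set(s))))
    )
    reports["outcomes"] = reports["primaryid"].map(codes).fillna("")
    reports["serious"] = reports["outcomes"].apply(
        lambda s: bool(SERIOUS_OUTCOMES & set(s.split(","))) if s else False
    )

    drugs = pd.DataFrame(
        {
            "primaryid": raw.drug["PRIMARYID"].astype(str),
            "drug_seq": raw.drug.get("DRUG_SEQ", pd.Series("", index=raw.drug.index)).astype(str),
            "role": raw.drug["ROLE_COD"].astype(str).str.strip().str.upper(),
            "drugname": raw.drug["DRUGNAME"].astype(str).str.strip(),
        }
    )
    ther = raw.ther
    start_key, _ = _date_keys(ther["START_DT"])
    starts = pd.DataFrame(
        {
            "primaryid": ther["PRIMARYID"].astype(str),
            "drug_seq": ther.get("DSG_SEQ", pd.Series("", index=ther.index)).astype(str),
            "start_dt": ther["START_DT"].astype(str).str.strip(),
            "start_dt_key": start_key,
        }
    )
    starts["start_date"] = pd.to_datetime(
        starts["start_dt"].where(starts["start_dt"].str.len() == 8),
        format="%Y%m%d", errors="coerce",
    )
    drugs = drugs.merge(starts, on=["primaryid", "drug_seq"], how="left")

    reactions = pd.DataFrame(
        {
            "primaryid": raw.reac["PRIMARYID"].astype(str),
            "pt": normalize_pt(raw.reac["PT"]),
        }
    )
    reactions = reactions[reactions["pt"] != ""].drop_duplicates().reset_index(drop=True)
    return reports, drugs, reactions


def age_group(age_years: pd.Series) -> pd.Series:
    """Bin completed years into the strata <18, 18-44, 45-64, 65-74, >=75."""
    bins = [-np.inf, 18, 45, 65, 75, np.inf]
    labels = ["<18", "18-44", "45-64", "65-74", ">=75"]
    out = pd.cut(age_years, bins=bins, labels=labels, right=False).astype(object)
    return pd.Series(np.where(age_years.isna(), "unknown", out), index=age_years.index)


def normalize_pt(values: pd.Series | str) -> pd.Series | str:
    """Case-normalise a MedDRA preferred term: trimmed, single-spaced,
    first letter capitalised, remainder lower-case."""
    if isinstance(values, str):
        s = " ".join(values.split())
        return s[:1].upper() + s[1:].lower()
    s = values.astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    return s.str.slice(0, 1).str.upper() + s.str.slice(1).str.lower()


def dedup_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Keep one report per CASEID: maximal FDA_DT, ties broken by the highest
    PRIMARYID. Idempotent; empty input passes through."""
    if reports.empty:
        return reports.copy()
    pid_num = pd.to_numeric(reports["primaryid"], errors="coerce")
    ordered = reports.assign(_pid=pid_num.fillna(-1)).sort_values(
        ["caseid", "fda_dt", "_pid", "primaryid"], kind="mergesort"
    )
    keep = ordered.drop_duplicates("caseid", keep="last").drop(columns="_pid")
    return keep.sort_values("primaryid", kind="mergesort").reset_index(drop=True)


def drop_field_duplicates(reports: pd.DataFrame) -> pd.DataFrame:
    """Remove suspected re-entries of the same event under different case
    numbers: reports agreeing on age, sex, country and event date (all four
    present) keep only the earliest FDA_DT (tie: lowest PRIMARYID). Reports
    with any missing key field are never dropped.
    """
    if reports.empty:
        return reports.copy()
    eligible = (
        reports["age_years"].notna()
        & (reports["sex"] != "unknown")
        & (reports["country"] != "")
        & (reports["event_dt_precision"] > 0)
    )
    dup_pool = reports[eligible]
    pid_num = pd.to_numeric(dup_pool["primaryid"], errors="coerce").fillna(np.inf)
    ordered = dup_pool.assign(_pid=pid_num).sort_values(
        ["fda_dt", "_pid", "primaryid"], kind="mergesort"
    )
    keep_ids = ordered.drop_duplicates(
        ["age_years", "sex", "country", "event_dt"], keep="first"
    )["primaryid"]
    mask = ~eligible | reports["primaryid"].isin(keep_ids)
    return reports[mask].reset_index(drop=True)


def target_primaryids(
    drugs: pd.DataFrame,
    synonyms: list[str] | tuple[str, ...],
    substring: bool = False,
    role: str = "PS",
) -> set[str]:
    """PRIMARYIDs whose report names the target drug with the given role.

    Matching is case-insensitive on whitespace-trimmed names; exact by
    default, substring when requested.
    """
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    syn = [s.strip().upper() for s in synonyms]
    names = drugs["drugname"].str.strip().str.upper()
    if substring:
        hit = names.apply(lambda x: any(s in x for s in syn))
    else:
        hit = names.isin(syn)
    hit &= drugs["role"] == role
    return set(drugs.loc[hit, "primaryid"])


def select_target_reports(
    reports: pd.DataFrame,
    drugs: pd.DataFrame,
    synonyms: list[str] | tuple[str, ...],
    substring: bool = False,
) -> pd.DataFrame:
    """Subset of ``reports`` with the target drug as primary suspect."""
    ids = target_primaryids(drugs, synonyms, substring=substring)
    return reports[reports["primaryid"].isin(ids)].reset_index(drop=True)


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (PT, SOC) into a PT -> SOC dictionary.

    PTs are case-normalised like reaction terms; duplicate PT keys are a load
    error because each PT has exactly one primary SOC.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: PT->SOC map needs two columns (PT, SOC)")
    pts = normalize_pt(df.iloc[:, 0])
    if pts.duplicated().any():
        dupes = sorted(pts[pts.duplicated()].unique())
        raise ValueError(f"PT->SOC map has duplicate PT keys: {dupes[:5]}")
    return dict(zip(pts, df.iloc[:, 1].str.strip()))


def map_pts(
    reactions: pd.DataFrame, pt_soc_map: dict[str, str], policy: str = "keep"
) -> pd.DataFrame:
    """Annotate each reaction with its system organ class.

    policy="keep" labels unmapped PTs with the sentinel "UNMAPPED";
    policy="strict" raises on the first unmapped PT. The number of unmapped
    mentions is logged either way.
    """
    soc = reactions["pt"].map(pt_soc_map)
    n_unmapped = int(soc.isna().sum())
    if n_unmapped:
        if policy == "strict":
            missing = sorted(reactions.loc[soc.isna(), "pt"].unique())
            raise KeyError(f"{n_unmapped} reaction(s) with unmapped PTs: {missing[:5]}")
        logger.warning("%d reaction(s) mapped to sentinel SOC 'UNMAPPED'", n_unmapped)
    out = reactions.copy()
    out["soc"] = soc.fillna("UNMAPPED")
    return out
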