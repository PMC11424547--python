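"""Synthetic FAERS-dialect spontaneous-report generator with known ground truth.

Emulates the structure of the FDA Adverse Event Reporting System quarterly
ASCII releases — DEMO/DRUG/REAC/OUTC/THER tables, $-delimited — with planted
reporting-rate ratios, injected duplicate records, partial dates, age-unit
codes and per-field missingness, so every downstream pipeline stage can be
validated against a manifest of what was actually generated.

The generative model: each report independently receives a primary-suspect
(PS) drug (the target drug with probability ``drug_share``, otherwise a
background drug), demographics drawn from configured categorical
distributions, a therapy start date, an event date offset by a time-to-onset
draw, outcome codes, and a set of MedDRA preferred terms. Each background PT
has a baseline reporting probability; in target-drug reports that probability
is multiplied by the planted rate ratio (clipped to 1), which is exactly the
disproportionality the downstream statistics estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FaersTables",
    "default_background",
    "default_demographics",
    "generate",
    "write_faers_tables",
    "write_ground_truth",
    "write_config",
    "TARGET_SYNONYMS",
]

TARGET_SYNONYMS = ("TEDUGLUTIDE", "GATTEX", "REVESTIVE")

# a subset of the 27 MedDRA system organ classes, used by the default panel
SOC_POOL = (
    "Gastrointestinal disorders",
    "Infections and infestations",
    "Metabolism and nutrition disorders",
    "Investigations",
    "General disorders and administration site conditions",
    "Renal and urinary disorders",
    "Surgical and medical procedures",
    "Injury, poisoning and procedural complications",
    "Hepatobiliary disorders",
    "Nervous system disorders",
)

_BACKGROUND_DRUGS = tuple(f"COMPARATOR_{i:02d}" for i in range(1, 41))

_COUNTRY_OTHER = ("GB", "IT", "ES", "AU", "NL", "BE", "CH", "SE", "DK", "AT")


def default_background(n_terms: int = 50) -> list[tuple[str, str, float]]:
    """Deterministic background PT panel: names, SOCs, log-spread baselines.

    Baseline reporting probabilities span 0.002-0.08, the range typical of
    common-to-frequent adverse-event terms in a single-drug stratum.
    """
    probs = np.geomspace(0.002, 0.08, n_terms)
    return [
        (f"Pt {i:03d}", SOC_POOL[i % len(SOC_POOL)], float(probs[i]))
        for i in range(n_terms)
    ]


def default_demographics() -> dict[str, dict[str, float]]:
    """Report-level categorical distributions mirroring a real teduglutide cohort:

    females predominate (~57%), age is unknown for ~42% of reports with the
    45-64 stratum the largest known group, consumers and other health
    professionals dominate reporting, and the US contributes ~73% of reports.
    """
    return {
        "sex": {"F": 0.5651, "M": 0.3420, "UNK": 0.0929},
        "age_group": {
            "<18": 0.0810, "18-44": 0.0856, "45-64": 0.2355,
            "65-74": 0.1218, ">=75": 0.0518, "unknown": 0.4243,
        },
        "reporter": {"CN": 0.4035, "PH": 0.0257, "MD": 0.1582, "OT": 0.3970, "UNK": 0.0156},
        "country": {
            "US": 0.7267, "DE": 0.0712, "FR": 0.0658, "JP": 0.0253,
            "CA": 0.0219, "OTHER": 0.0891,
        },
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic database."""

    n_reports: int = 10_000
    drug_share: float = 0.1
    background_pts: list[tuple[str, str, float]] = field(default_factory=default_background)
    planted_signals: list[tuple[str, float]] = field(default_factory=list)
    pediatric_signals: list[tuple[str, float]] = field(default_factory=list)
    demographics: dict[str, dict[str, float]] = field(default_factory=default_demographics)
    serious_outcome_probs: dict[str, float] = field(
        default_factory=lambda: {
            "HO": 0.3711, "DE": 0.0494, "LT": 0.0100, "DS": 0.0044,
            "CA": 0.0010, "RI": 0.0010, "OT": 0.2500,
        }
    )
    # time from therapy start to event, in days: a two-piece lognormal whose
    # lower and upper halves have separate spreads, so the median (~393 days)
    # and the asymmetric IQR (~97-996 days) of long-term dosing are both
    # matched; sigma = ln(median/q1)/0.6745 below, ln(q3/median)/0.6745 above
    onset_days_distribution: dict = field(
        default_factory=lambda: {
            "name": "split_lognormal", "mu": 5.9738, "sigma_lo": 2.0740, "sigma_hi": 1.3790,
        }
    )
    duplicate_rate: float = 0.03      # clones under a new CASEID (field-level duplicates)
    revision_rate: float = 0.03      # same-CASEID follow-up versions
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"event_dt": 0.25, "start_dt": 0.15, "country": 0.02}
    )
    partial_date_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not 0 <= self.drug_share <= 1:
            raise ValueError("drug_share must lie in [0, 1]")
        if not self.background_pts:
            raise ValueError("background_pts must be non-empty")
        known = {pt for pt, _, _ in self.background_pts}
        for pt, _, p in self.background_pts:
            if not 0 <= p <= 1:
                raise ValueError(f"background_pts: baseline probability of {pt!r} outside [0,1]")
        for pt, rr in self.planted_signals:
            if pt not in known:
                raise ValueError(f"planted_signals: {pt!r} not in background_pts")
            if rr < 0:
                raise ValueError(f"planted_signals: rate ratio for {pt!r} must be >= 0")
        for pt, mult in self.pediatric_signals:
            if pt not in known:
                raise ValueError(f"pediatric_signals: {pt!r} not in background_pts")
            if mult < 0:
                raise ValueError(f"pediatric_signals: multiplier for {pt!r} must be >= 0")
        for name, dist in self.demographics.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"demographics[{name!r}] probabilities sum to {tot}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"demographics[{name!r}] has a negative probability")
        for code, p in self.serious_outcome_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"serious_outcome_probs[{code!r}] outside [0,1]")
        for rate_name in ("duplicate_rate", "revision_rate", "partial_date_rate"):
            v = getattr(self, rate_name)
            if not 0 <= v <= 1:
                raise ValueError(f"{rate_name} must lie in [0, 1]")
        for fld, v in self.missing_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"missing_rates[{fld!r}] must lie in [0, 1]")
        dist = self.onset_days_distribution
        if dist.get("name") not in ("lognormal", "split_lognormal", "exponential"):
            raise ValueError(
                "onset_days_distribution: name must be 'lognormal', "
                "'split_lognormal' or 'exponential'"
            )
        if dist["name"] == "lognormal" and dist.get("sigma", 1.0) <= 0:
            raise ValueError("onset_days_distribution: sigma must be > 0")
        if dist["name"] == "split_lognormal" and (
            dist.get("sigma_lo", 1.0) <= 0 or dist.get("sigma_hi", 1.0) <= 0
        ):
            raise ValueError("onset_days_distribution: sigma_lo/sigma_hi must be > 0")
        if dist["name"] == "exponential" and dist.get("scale", 1.0) <= 0:
            raise ValueError("onset_days_distribution: scale must be > 0")


class FaersTables(NamedTuple):
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the pipeline."""

    rate_ratio: dict[str, float]                       # per-PT planted RR (1.0 = null)
    target_primaryids: list[str]
    field_duplicate_pairs: list[tuple[str, str]]       # (original, clone) primaryids
    revision_pairs: list[tuple[str, str]]              # (old, new) primaryids, same caseid
    serious: dict[str, bool]                           # per original report


_AGE_RANGES = {
    "<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64),
    "65-74": (65, 74), ">=75": (75, 95),
}


def _sample_categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    cats = list(dist.keys())
    p = np.array([dist[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(cats, dtype=object), size=n, p=p)


def _onset_days(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    if dist["name"] == "lognormal":
        d = rng.lognormal(mean=dist["mu"], sigma=dist["sigma"], size=n)
    elif dist["name"] == "split_lognormal":
        z = rng.standard_normal(n)
        sigma = np.where(z < 0, dist["sigma_lo"], dist["sigma_hi"])
        d = np.exp(dist["mu"] + sigma * z)
    else:
        d = rng.exponential(scale=dist["scale"], size=n)
    # cap at 30 years: keeps dates plausible, leaves median/IQR untouched
    return np.clip(d.astype(int), 0, 10_957)


def _fmt_dates(days_since_epoch: np.ndarray) -> np.ndarray:
    dt = pd.to_datetime(days_since_epoch, unit="D", origin="unix")
    return dt.strftime("%Y%m%d").to_numpy(dtype=object)


def generate(config: SimConfig) -> tuple[FaersTables, GroundTruth]:
    """Generate one synthetic FAERS-style database.

    Returns the five raw tables (all columns as strings, "" for missing) and
    the ground-truth manifest. Identical config and seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    caseid = np.array([f"{10_000_000 + i}" for i in range(n)], dtype=object)
    primaryid = np.array([f"{10_000_000 + i}1" for i in range(n)], dtype=object)
    target = rng.random(n) < config.drug_share

    # demographics
    sex = _sample_categorical(rng, config.demographics["sex"], n)
    age_group = _sample_categorical(rng, config.demographics["age_group"], n)
    reporter = _sample_categorical(rng, config.demographics["reporter"], n)
    country = _sample_categorical(rng, config.demographics["country"], n)
    other_mask = country == "OTHER"
    country[other_mask] = rng.choice(
        np.array(_COUNTRY_OTHER, dtype=object), size=int(other_mask.sum())
    )

    # age in years, with a FAERS unit code; young children get MON/DY codes to
    # exercise downstream unit harmonisation
    age_val = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    known_age = age_group != "unknown"
    ages = np.zeros(n)
    for grp, (lo, hi) in _AGE_RANGES.items():
        m = age_group == grp
        ages[m] = rng.integers(lo, hi + 1, size=int(m.sum()))
    unit_pick = rng.random(n)
    for i in np.flatnonzero(known_age):
        a = ages[i]
        if a <= 2 and unit_pick[i] < 0.5:
            age_val[i], age_cod[i] = str(int(a * 12)), "MON"
        elif a <= 2:
            age_val[i], age_cod[i] = str(int(a * 365)), "DY"
        elif unit_pick[i] < 0.02:
            age_val[i], age_cod[i] = str(int(a * 12)), "MON"
        else:
            age_val[i], age_cod[i] = str(int(a)), "YR"

    # dates: therapy start, event = start + onset, FDA receipt after the event
    start_days = rng.integers(15706, 18628, size=n)  # 2013-01-01 .. 2021-01-01
    onset = _onset_days(rng, config.onset_days_distribution, n)
    event_days = start_days + onset
    fda_days = event_days + rng.integers(7, 181, size=n)
    start_dt = _fmt_dates(start_days)
    event_dt = _fmt_dates(event_days)
    fda_dt = _fmt_dates(fda_days)

    # partial event dates (YYYYMM / YYYY) at the configured rate
    partial = rng.random(n) < config.partial_date_rate
    halves = rng.random(n) < 0.5
    for i in np.flatnonzero(partial):
        event_dt[i] = event_dt[i][:6] if halves[i] else event_dt[i][:4]

    # missingness
    for fld, rate in config.missing_rates.items():
        m = rng.random(n) < rate
        if fld == "event_dt":
            event_dt[m] = ""
        elif fld == "start_dt":
            start_dt[m] = ""
        elif fld == "country":
            country[m] = ""
        elif fld == "sex":
            sex[m] = ""

    # PT incidence: Bernoulli per (report, term) with planted multipliers
    pts = [pt for pt, _, _ in config.background_pts]
    base = np.array([p for _, _, p in config.background_pts])
    probs = np.tile(base, (n, 1))
    planted = dict(config.planted_signals)
    pediatric = ages < 18
    for j, pt in enumerate(pts):
        if pt in planted:
            probs[target, j] = min(base[j] * planted[pt], 1.0)
    for pt, mult in config.pediatric_signals:
        j = pts.index(pt)
        m = target & known_age & pediatric
        probs[m, j] = np.minimum(probs[m, j] * mult, 1.0)
    hits = rng.random((n, len(pts))) < probs
    # every report carries at least one PT
    empty = ~hits.any(axis=1)
    if empty.any():
        forced = rng.choice(len(pts), size=int(empty.sum()), p=base / base.sum())
        hits[np.flatnonzero(empty), forced] = True

    # outcomes: independent per-code Bernoulli
    out_codes = list(config.serious_outcome_probs.keys())
    out_hits = rng.random((n, len(out_codes))) < np.array(
        [config.serious_outcome_probs[c] for c in out_codes]
    )
    serious_true = {
        primaryid[i]: bool(
            any(out_hits[i, j] for j, c in enumerate(out_codes) if c in ("DE", "LT", "HO", "DS"))
        )
        for i in range(n)
    }

    # drug names: target reports carry a synonym as PS; everyone gets a
    # background PS otherwise, plus 0-2 concomitants; a small fraction of
    # non-target reports mention the target with a non-suspect role
    syn_pick = rng.integers(0, len(TARGET_SYNONYMS), size=n)
    bg_pick = rng.integers(0, len(_BACKGROUND_DRUGS), size=n)
    n_concom = rng.integers(0, 3, size=n)
    concom_pick = rng.integers(0, len(_BACKGROUND_DRUGS), size=(n, 2))
    target_as_concom = (~target) & (rng.random(n) < 0.01)

    demo = pd.DataFrame(
        {
            "PRIMARYID": primaryid, "CASEID": caseid, "FDA_DT": fda_dt,
            "EVENT_DT": event_dt, "SEX": sex, "AGE": age_val, "AGE_COD": age_cod,
            "OCCP_COD": np.where(reporter == "UNK", "", reporter),
            "OCCR_COUNTRY": country,
            "REPORTER_COUNTRY": np.where(country == "", "US", country),
        }
    )

    drug_rows: list[tuple] = []
    ther_rows: list[tuple] = []
    for i in range(n):
        ps_name = TARGET_SYNONYMS[syn_pick[i]] if target[i] else _BACKGROUND_DRUGS[bg_pick[i]]
        drug_rows.append((primaryid[i], "1", "PS", ps_name))
        ther_rows.append((primaryid[i], "1", start_dt[i]))
        seq = 2
        for k in range(n_concom[i]):
            drug_rows.append((primaryid[i], str(seq), "C", _BACKGROUND_DRUGS[concom_pick[i, k]]))
            seq += 1
        if target_as_concom[i]:
            drug_rows.append((primaryid[i], str(seq), "C", TARGET_SYNONYMS[syn_pick[i]]))
    drug = pd.DataFrame(drug_rows, columns=["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"])
    ther = pd.DataFrame(ther_rows, columns=["PRIMARYID", "DSG_SEQ", "START_DT"])

    rep_idx, pt_idx = np.nonzero(hits)
    reac = pd.DataFrame(
        {"PRIMARYID": primaryid[rep_idx], "PT": np.array(pts, dtype=object)[pt_idx]}
    )
    o_rep, o_idx = np.nonzero(out_hits)
    outc = pd.DataFrame(
        {"PRIMARYID": primaryid[o_rep], "OUTC_COD": np.array(out_codes, dtype=object)[o_idx]}
    )

    tables = FaersTables(demo=demo, drug=drug, reac=reac, outc=outc, ther=ther)

    # same-CASEID revisions: exact copies except PRIMARYID (version bump) and a
    # later FDA_DT — the CASEID dedup rule must keep the revision
    rev_mask = rng.random(n) < config.revision_rate
    rev_delay = rng.integers(10, 301, size=n)
    rev_idx = np.flatnonzero(rev_mask)
    revisions = [(primaryid[i], f"{caseid[i]}2") for i in rev_idx]

    # field-level duplicates: same report re-entered under a brand-new case
    # number; only the field-matching rule (age/sex/country/event date) can
    # catch these. Cloned from target reports with all four keys present.
    complete = (
        target & known_age & np.isin(sex, ("F", "M")) & (country != "")
        & np.array([len(e) == 8 for e in event_dt])
    )
    # a report receives at most one duplicate kind: a same-CASEID revision
    # would replace the original's PRIMARYID during dedup and muddle the
    # field-duplicate bookkeeping
    dup_mask = (rng.random(n) < config.duplicate_rate) & complete & ~rev_mask
    dup_delay = rng.integers(30, 301, size=n)
    dup_idx = np.flatnonzero(dup_mask)
    dup_pairs = [(primaryid[i], f"{90_000_000 + k}1") for k, i in enumerate(dup_idx)]

    mapping = pd.DataFrame(
        {
            "PRIMARYID": [primaryid[i] for i in rev_idx] + [primaryid[i] for i in dup_idx],
            "_new_pid": [p for _, p in revisions] + [p for _, p in dup_pairs],
            "_new_case": [caseid[i] for i in rev_idx]
            + [f"{90_000_000 + k}" for k in range(len(dup_idx))],
            "_new_fda": list(_fmt_dates(fda_days[rev_idx] + rev_delay[rev_idx]))
            + list(_fmt_dates(fda_days[dup_idx] + dup_delay[dup_idx])),
        }
    )
    if len(mapping):
        tables = _clone_reports(tables, mapping)

    truth = GroundTruth(
        rate_ratio={pt: float(planted.get(pt, 1.0)) for pt in pts},
        target_primaryids=[primaryid[i] for i in np.flatnonzero(target)],
        field_duplicate_pairs=dup_pairs,
        revision_pairs=revisions,
        serious=serious_true,
    )
    return tables, truth


def _clone_reports(tables: FaersTables, mapping: pd.DataFrame) -> FaersTables:
    """Re-emit the mapped reports under new identifiers; other fields identical."""
    out = []
    for name, tab in tables._asdict().items():
        c = tab.merge(mapping, on="PRIMARYID", how="inner")
        c["PRIMARYID"] = c["_new_pid"]
        if name == "demo":
            c["CASEID"] = c["_new_case"]
            c["FDA_DT"] = c["_new_fda"]
        c = c.drop(columns=["_new_pid", "_new_case", "_new_fda"])
        out.append(pd.concat([tab, c], ignore_index=True))
    return FaersTables(*out)


_FILES = {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt",
          "outc": "OUTC.txt", "ther": "THER.txt"}


def write_faers_tables(tables: FaersTables, directory: str | Path) -> dict[str, Path]:
    """Write the five tables in the FAERS ASCII dialect ($-delimited, header row).

    The dialect has no quoting, so any field containing the delimiter is
    rejected with a ValueError.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in _FILES.items():
        tab: pd.DataFrame = getattr(tables, name)
        for col in tab.columns:
            bad = tab[col].astype(str).str.contains(r"\$", regex=True)
            if bad.any():
                raise ValueError(
                    f"{name}.{col} contains the '$' delimiter in {int(bad.sum())} row(s); "
                    "the FAERS ASCII dialect has no quoting"
                )
        path = directory / fname
        tab.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path
    return paths


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write the manifest as plain TSVs next to the generated tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    rr = pd.DataFrame(sorted(truth.rate_ratio.items()), columns=["pt", "rate_ratio"])
    paths["rate_ratio"] = directory / "truth_rate_ratio.tsv"
    rr.to_csv(paths["rate_ratio"], sep="\t", index=False)
    dups = pd.DataFrame(
        [("field", o, d) for o, d in truth.field_duplicate_pairs]
        + [("revision", o, d) for o, d in truth.revision_pairs],
        columns=["kind", "original_primaryid", "duplicate_primaryid"],
    )
    paths["duplicates"] = directory / "truth_duplicates.tsv"
    dups.to_csv(paths["duplicates"], sep="\t", index=False)
    ser = pd.DataFrame(sorted(truth.serious.items()), columns=["primaryid", "serious"])
    paths["serious"] = directory / "truth_serious.tsv"
    ser.to_csv(paths["serious"], sep="\t", index=False)
    tgt = pd.DataFrame({"primaryid": truth.target_primaryids})
    paths["target"] = directory / "truth_target.tsv"
    tgt.to_csv(paths["target"], sep="\t", index=False)
    return paths


def write_config(config: SimConfig, path: str | Path) -> Path:
    """Echo the configuration as JSON so every run is auditable."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
    return path
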