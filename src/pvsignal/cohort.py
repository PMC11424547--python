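"""Descriptive and comparative cohort statistics for a target-drug report set.

Covers the demographic summary (sex, age strata, reporter occupation,
occurrence country, outcome codes, reporting year), time-to-onset analysis
(days from the earliest primary-suspect therapy start to the event), serious
vs non-serious contrasts by Pearson chi-square, and within-drug
pediatric-vs-adult disproportionality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .disprop import ContingencyTable, ror

__all__ = [
    "pct_round",
    "demographic_summary",
    "onset_analysis",
    "OnsetSummary",
    "serious_contrast",
    "subgroup_disprop",
    "ONSET_BINS",
]

# closed bins in days, with everything beyond 360 open-ended
ONSET_BINS = ["0-30", "31-60", "61-90", "91-180", "181-360", ">360"]
_ONSET_EDGES = [0, 30, 60, 90, 180, 360]


def pct_round(count: float, denom: float) -> float:
    """Percentage rounded half-up to 2 decimals (the convention of printed
    report tables, where e.g. 5715/10114 -> 56.51)."""
    if denom == 0:
        return math.nan
    return math.floor(count / denom * 10000 + 0.5) / 100


def _section(counts: pd.Series, section: str, denom: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "section": section,
            "category": counts.index.astype(str),
            "count": counts.to_numpy(),
            "denominator": denom,
            "pct": [pct_round(c, denom) for c in counts],
        }
    )


def demographic_summary(reports: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by sex, age group, reporter, country, outcome
    code and reporting year.

    Percentages are against the total report count; outcome rows additionally
    carry ``pct_of_entries`` against the total number of outcome entries,
    because a report can have several outcomes and published tables are not
    always explicit about which denominator they use. Both denominators are
    reported as columns.
    """
    n = len(reports)
    if n == 0:
        return pd.DataFrame(
            columns=["section", "category", "count", "denominator", "pct", "pct_of_entries"]
        )
    parts = []
    order = {
        "sex": ["female", "male", "unknown"],
        "age_group": ["<18", "18-44", "45-64", "65-74", ">=75", "unknown"],
        "reporter": ["consumer", "pharmacist", "physician", "other health professional", "unknown"],
    }
    for col, cats in order.items():
        counts = reports[col].value_counts().reindex(cats, fill_value=0)
        parts.append(_section(counts, col, n))

    country = reports["country"].replace("", "unknown").value_counts()
    parts.append(_section(country, "country", n))

    year = (reports["fda_dt"] // 10_000).astype("Int64").value_counts().sort_index()
    parts.append(_section(year, "year", n))

    codes = reports["outcomes"].str.split(",").explode()
    codes = codes[codes != ""]
    n_entries = len(codes)
    out_counts = codes.value_counts().sort_index()
    out_df = _section(out_counts, "outcome", n)
    out_df["pct_of_entries"] = [pct_round(c, n_entries) for c in out_counts]
    out_df["entries_denominator"] = n_entries
    parts.append(out_df)

    serious = reports["serious"].sum()
    parts.append(_section(pd.Series({"serious": serious}), "serious", n))

    df = pd.concat(parts, ignore_index=True)
    return df


@dataclass
class OnsetSummary:
    median: float
    q1: float
    q3: float
    n_included: int
    n_excluded_missing: int
    n_excluded_negative: int
    bin_counts: pd.Series


def onset_analysis(
    reports: pd.DataFrame, drugs: pd.DataFrame, synonyms=None, substring: bool = False
) -> tuple[pd.DataFrame, OnsetSummary]:
    """Time from the earliest primary-suspect therapy start to the event.

    Uses day-precision dates only; records with a missing start or event date
    (or coarser precision) are excluded and counted, as are negative deltas.
    Quartiles are linearly interpolated. Returns the per-report onset records
    and a summary with the bin counts over 0-30/31-60/61-90/91-180/181-360/>360.
    """
    ps = drugs[drugs["role"] == "PS"]
    if synonyms:
        from .ingest import target_primaryids

        ids = target_primaryids(drugs, synonyms, substring=substring)
        ps = ps[ps["primaryid"].isin(ids)]
    starts = ps.dropna(subset=["start_date"]).groupby("primaryid")["start_date"].min()

    rec = reports[["primaryid", "event_date"]].copy()
    rec["start_date"] = rec["primaryid"].map(starts)
    missing = rec["event_date"].isna() | rec["start_date"].isna()
    rec["onset_days"] = (rec["event_date"] - rec["start_date"]).dt.days
    negative = (~missing) & (rec["onset_days"] < 0)
    included = rec[~missing & ~negative].copy()
    included["bin"] = bin_onset(included["onset_days"])

    if len(included):
        q1, med, q3 = np.percentile(included["onset_days"], [25, 50, 75])
    else:
        q1 = med = q3 = math.nan
    counts = included["bin"].value_counts().reindex(ONSET_BINS, fill_value=0)
    summary = OnsetSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        n_included=int(len(included)),
        n_excluded_missing=int(missing.sum()),
        n_excluded_negative=int(negative.sum()),
        bin_counts=counts,
    )
    return included[["primaryid", "onset_days", "bin"]].reset_index(drop=True), summary


def bin_onset(days: pd.Series) -> pd.Series:
    """Assign onset day counts to the reporting-interval bins."""
    edges = [-0.5] + [e + 0.5 for e in _ONSET_EDGES[1:]] + [np.inf]
    return pd.cut(days, bins=edges, labels=ONSET_BINS).astype(object)


def _pearson(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square without continuity correction; returns
    (chi2, p, low_expected_flag). Degenerate margins give (nan, nan, True)."""
    table = np.asarray(table)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan, math.nan, True
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), bool((expected < 5).any())


def serious_contrast(
    reports: pd.DataFrame, reactions: pd.DataFrame, top_k_terms: int = 30
) -> dict[str, pd.DataFrame]:
    """Serious vs non-serious contrasts for gender, age strata and the most
    frequent preferred terms.

    For each contrast the counts in serious and non-serious reports are
    tabulated with column percentages, and a two-sided Pearson chi-square
    p-value is attached (gender and age as single multi-row tables; each PT
    as its own 2x2 of term presence x seriousness). Cells with expected
    count < 5 are flagged rather than corrected. ``significant`` marks
    p < 0.001.
    """
    serious = reports["serious"].astype(bool)
    n_ser, n_non = int(serious.sum()), int((~serious).sum())

    out: dict[str, pd.DataFrame] = {}

    def _grouped(col: str, cats: list[str], name: str) -> None:
        known = reports[reports[col].isin(cats)]
        tab = pd.crosstab(known[col], known["serious"].astype(bool)).reindex(
            cats, fill_value=0
        )
        ser = tab.get(True, pd.Series(0, index=tab.index))
        non = tab.get(False, pd.Series(0, index=tab.index))
        mat = np.column_stack([ser, non])
        if mat.sum() and (mat.sum(axis=1) > 0).sum() >= 2 and (mat.sum(axis=0) > 0).sum() >= 2:
            chi2, p, low = _pearson(mat[mat.sum(axis=1) > 0])
        else:
            chi2, p, low = math.nan, math.nan, True
        out[name] = pd.DataFrame(
            {
                "category": cats,
                "serious_n": ser.to_numpy(),
                "serious_pct": [pct_round(x, ser.sum()) for x in ser],
                "nonserious_n": non.to_numpy(),
                "nonserious_pct": [pct_round(x, non.sum()) for x in non],
                "chi2": chi2,
                "p": p,
                "low_expected": low,
                "significant": (p < 0.001) if p == p else False,
            }
        )

    _grouped("sex", ["female", "male"], "gender")
    _grouped("age_group", ["<18", "18-44", "45-64", "65-74", ">=75"], "age")

    pairs = reactions[["primaryid", "pt"]].drop_duplicates().merge(
        reports[["primaryid", "serious"]], on="primaryid", how="inner"
    )
    top = pairs["pt"].value_counts().head(top_k_terms).index
    rows = []
    for pt in top:
        with_term = pairs.loc[pairs["pt"] == pt, "primaryid"]
        a = int(pairs[(pairs["pt"] == pt) & pairs["serious"]]["primaryid"].nunique())
        c = int(with_term.nunique()) - a
        mat = np.array([[a, n_ser - a], [c, n_non - c]])
        if mat.min() >= 0 and n_ser > 0 and n_non > 0:
            chi2, p, low = _pearson(mat)
        else:
            chi2, p, low = math.nan, math.nan, True
        rows.append(
            {
                "pt": pt,
                "serious_n": a,
                "serious_pct": pct_round(a, n_ser),
                "nonserious_n": c,
                "nonserious_pct": pct_round(c, n_non),
                "chi2": chi2,
                "p": p,
                "low_expected": low,
                "significant": (p < 0.001) if p == p else False,
            }
        )
    out["pts"] = pd.DataFrame(rows)
    return out


def subgroup_disprop(
    reports: pd.DataFrame,
    reactions: pd.DataFrame,
    cutoff_age: float = 18.0,
    min_count: int = 5,
) -> pd.DataFrame:
    """Pediatric-vs-adult disproportionality within the target drug's reports.

    For each term, a 2x2 of (age < cutoff vs age >= cutoff) x (term vs not)
    over reports with known age, summarised as a reporting odds ratio with
    95% CI: a lower bound above 1 means pediatric-enriched, an upper bound
    below 1 adult-enriched. Zero margins leave the term flagged undefined
    (NaN statistics).
    """
    known = reports[reports["age_years"].notna()].copy()
    known["pediatric"] = known["age_years"] < cutoff_age
    n_ped = int(known["pediatric"].sum())
    n_adult = len(known) - n_ped

    pairs = reactions[["primaryid", "pt"]].drop_duplicates().merge(
        known[["primaryid", "pediatric"]], on="primaryid", how="inner"
    )
    counts = pairs.groupby("pt")["pediatric"].agg(["sum", "count"])
    rows = []
    for pt, row in counts.iterrows():
        a = int(row["sum"])
        c = int(row["count"] - row["sum"])
        if a + c < min_count:
            continue
        if n_ped == 0 or n_adult == 0:
            est = lo = hi = math.nan
        else:
            est, lo, hi = ror(ContingencyTable(a, n_ped - a, c, n_adult - c))
        rows.append(
            {"pt": pt, "pediatric_n": a, "adult_n": c, "ror": est, "ci_lo": lo, "ci_hi": hi}
        )
    return pd.DataFrame(rows).sort_values("pediatric_n", ascending=False).reset_index(
        drop=True
    ) if rows else pd.DataFrame(
        columns=["pt", "pediatric_n", "adult_n", "ror", "ci_lo", "ci_hi"]
    )
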