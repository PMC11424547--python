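"""End-to-end orchestration: ingest -> dedup -> tables -> statistics -> screen.

The functions here tie the stages together exactly as a published FAERS
analysis proceeds: parse the quarterly tables, keep the latest version of
each case, select the target drug's primary-suspect reports, drop suspected
re-entries, build PT- and SOC-level contingency tables against the rest of
the database, compute the four disproportionality statistics, and apply the
consensus screening rules. Every stage's row counts land in a manifest so
each reported n is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import cohort, disprop, ingest, screen as screen_mod
from .disprop import BcpnnPriors
from .screen import ThresholdPolicy
from .simulate import FaersTables, TARGET_SYNONYMS

__all__ = ["PipelineConfig", "IngestResult", "SignalsResult", "ingest_database",
           "run_signals", "run_descriptives", "tables_from_memory", "write_results"]


@dataclass
class PipelineConfig:
    """Everything a signals run needs besides the data itself."""

    synonyms: tuple[str, ...] = TARGET_SYNONYMS
    pt_soc_map: dict[str, str] | str | Path | None = None
    min_count: int = 5
    pt_policy: ThresholdPolicy = dc_field(default_factory=ThresholdPolicy)
    soc_policy: ThresholdPolicy = dc_field(
        default_factory=lambda: ThresholdPolicy(combination="any_one")
    )
    unit: str = "report"
    correction: bool = True
    yates: bool = False
    bcpnn_priors: BcpnnPriors = dc_field(default_factory=BcpnnPriors)
    substring_match: bool = False
    top_k: int = 30
    unmapped_policy: str = "keep"

    def resolved_map(self) -> dict[str, str] | None:
        if self.pt_soc_map is None:
            return None
        if isinstance(self.pt_soc_map, (str, Path)):
            return ingest.load_pt_soc_map(self.pt_soc_map)
        return self.pt_soc_map


@dataclass
class IngestResult:
    reports: pd.DataFrame      # deduplicated database with boolean ``target``
    drugs: pd.DataFrame
    reactions: pd.DataFrame    # restricted to surviving reports, SOC-annotated if mapped
    manifest: dict


def tables_from_memory(tables: FaersTables) -> ingest.RawTables:
    """Adapt generator output to the parser's raw-table container."""
    return ingest.RawTables(
        demo=tables.demo, drug=tables.drug, reac=tables.reac,
        outc=tables.outc, ther=tables.ther, malformed={},
    )


def ingest_database(
    source: str | Path | ingest.RawTables | FaersTables,
    config: PipelineConfig = PipelineConfig(),
) -> IngestResult:
    """Parse, harmonise and deduplicate a database; flag target reports.

    The CASEID rule (latest FDA_DT, then highest PRIMARYID) runs over the
    whole database; the field-based duplicate rule (identical age, sex,
    country and event date) runs only within the target drug's
    primary-suspect reports, mirroring how a single-drug study screens its
    own cohort for re-entered cases.
    """
    if isinstance(source, FaersTables):
        raw = tables_from_memory(source)
    elif isinstance(source, ingest.RawTables):
        raw = source
    else:
        raw = ingest.parse_tables(source)
    reports, drugs, reactions = ingest.harmonize(raw)
    n_parsed = len(reports)

    reports = ingest.dedup_reports(reports)
    n_dedup = len(reports)

    tgt_ids = ingest.target_primaryids(
        drugs, config.synonyms, substring=config.substring_match
    )
    is_target = reports["primaryid"].isin(tgt_ids)
    targets = ingest.drop_field_duplicates(reports[is_target])
    n_target_before = int(is_target.sum())
    database = pd.concat([reports[~is_target], targets], ignore_index=True)
    database = database.sort_values("primaryid", kind="mergesort").reset_index(drop=True)
    database["target"] = database["primaryid"].isin(tgt_ids)

    reactions = reactions[reactions["primaryid"].isin(database["primaryid"])]
    mapping = config.resolved_map()
    if mapping is not None:
        reactions = ingest.map_pts(reactions, mapping, policy=config.unmapped_policy)
    reactions = reactions.reset_index(drop=True)

    manifest = {
        "parsed": n_parsed,
        "malformed": dict(raw.malformed),
        "after_caseid_dedup": n_dedup,
        "target_before_field_dedup": n_target_before,
        "target": int(len(targets)),
        "database": int(len(database)),
        "reactions": int(len(reactions)),
    }
    return IngestResult(reports=database, drugs=drugs, reactions=reactions, manifest=manifest)


@dataclass
class SignalsResult:
    scores_pt: pd.DataFrame
    scores_soc: pd.DataFrame
    screened_pt: pd.DataFrame
    screened_soc: pd.DataFrame
    top_by_count: pd.DataFrame
    top_by_ebgm: pd.DataFrame
    prior_pt: disprop.PriorHyperparams | None
    manifest: dict


def run_signals(
    source: str | Path | ingest.RawTables | FaersTables,
    config: PipelineConfig = PipelineConfig(),
) -> SignalsResult:
    """Full signal-detection run at PT and (when a map is given) SOC level.

    PT-level screening uses the strict all-four consensus rule and emits the
    two ranked tables (by report count and by EBGM among EBGM05 > 2
    survivors); SOC-level screening uses the permissive any-one rule.
    """
    ing = ingest_database(source, config)
    if not ing.reports["target"].any():
        raise ValueError("no target-drug reports found for the given synonyms")

    tables_pt = disprop.build_tables(
        ing.reports, ing.reactions, level="PT",
        min_count=config.min_count, unit=config.unit,
    )
    prior = disprop.fit_mgps_prior(tables_pt) if len(tables_pt) >= 2 else None
    scores_pt = disprop.score_tables(
        tables_pt, prior=prior, bcpnn_priors=config.bcpnn_priors,
        correction=config.correction, yates=config.yates,
    )
    screened_pt = screen_mod.screen(scores_pt, config.pt_policy)
    flagged = screened_pt[screened_pt["signal"]]
    top_by_count = screen_mod.rank(flagged, key="report_count", top_k=config.top_k)
    top_by_ebgm = screen_mod.rank(
        flagged[flagged["ebgm05"] > config.pt_policy.ebgm05_min],
        key="ebgm", top_k=config.top_k,
    )

    if "soc" in ing.reactions.columns:
        tables_soc = disprop.build_tables(
            ing.reports, ing.reactions, level="SOC",
            min_count=config.min_count, unit=config.unit,
        )
        prior_soc = disprop.fit_mgps_prior(tables_soc) if len(tables_soc) >= 2 else None
        scores_soc = disprop.score_tables(
            tables_soc, prior=prior_soc, bcpnn_priors=config.bcpnn_priors,
            correction=config.correction, yates=config.yates,
        )
        screened_soc = screen_mod.screen(scores_soc, config.soc_policy)
    else:
        scores_soc = disprop.score_tables([])
        screened_soc = scores_soc

    manifest = dict(ing.manifest)
    manifest["terms_tested_pt"] = int(len(scores_pt))
    manifest["terms_tested_soc"] = int(len(scores_soc))
    manifest["signals_pt"] = int(screened_pt["signal"].sum()) if len(screened_pt) else 0
    manifest["signals_soc"] = int(screened_soc["signal"].sum()) if len(screened_soc) else 0
    return SignalsResult(
        scores_pt=scores_pt, scores_soc=scores_soc,
        screened_pt=screened_pt, screened_soc=screened_soc,
        top_by_count=top_by_count, top_by_ebgm=top_by_ebgm,
        prior_pt=prior, manifest=manifest,
    )


def run_descriptives(
    source: str | Path | ingest.RawTables | FaersTables,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Descriptive outputs over the target cohort: demographics, onset,
    serious contrasts and pediatric-vs-adult disproportionality."""
    ing = ingest_database(source, config)
    targets = ing.reports[ing.reports["target"]]
    if targets.empty:
        raise ValueError("no target-drug reports found for the given synonyms")
    reactions = ing.reactions[ing.reactions["primaryid"].isin(targets["primaryid"])]

    demo = cohort.demographic_summary(targets)
    onset_records, onset_summary = cohort.onset_analysis(
        targets, ing.drugs, synonyms=config.synonyms, substring=config.substring_match
    )
    contrasts = cohort.serious_contrast(targets, reactions, top_k_terms=config.top_k)
    subgroup = cohort.subgroup_disprop(targets, reactions, min_count=config.min_count)
    return {
        "demographics": demo,
        "onset_records": onset_records,
        "onset_summary": onset_summary,
        "serious_contrast": contrasts,
        "subgroup": subgroup,
        "manifest": ing.manifest,
    }


_RESULT_COLS = [
    "term", "a", "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi",
    "chi2", "ic", "ic025", "ebgm", "ebgm05", "p", "adjusted_p", "signal",
]


def write_results(result: SignalsResult, directory: str | Path) -> dict[str, Path]:
    """Write the screened score tables and ranked top-k tables as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    outputs = {
        "signals_pt.tsv": result.screened_pt,
        "signals_soc.tsv": result.screened_soc,
        "top_by_count.tsv": result.top_by_count,
        "top_by_ebgm.tsv": result.top_by_ebgm,
    }
    for fname, df in outputs.items():
        cols = [c for c in _RESULT_COLS if c in df.columns]
        path = directory / fname
        df[cols].round(6).to_csv(path, sep="\t", index=False)
        paths[fname] = path
    manifest = pd.Series(
        {k: v for k, v in result.manifest.items() if not isinstance(v, dict)}
    )
    paths["manifest.tsv"] = directory / "manifest.tsv"
    manifest.to_csv(paths["manifest.tsv"], sep="\t", header=False)
    return paths
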