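"""Threshold policies, signal screening and results-table ranking.

A drug-term pair is a signal when its disproportionality statistics exceed
the conventional pharmacovigilance thresholds. At the PT level the strict
consensus rule requires all four algorithms simultaneously; at the SOC level
the permissive rule accepts any one of the four.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ThresholdPolicy", "screen", "rank"]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-algorithm signal thresholds and the rule combining them.

    Defaults are the standard criteria: ROR lower 95% CI bound > 1;
    PRR >= 2 with chi-square >= 4; IC025 > 0; EBGM05 > 2; a term needs at
    least ``min_count`` reports to be evaluated at all.
    """

    min_count: int = 5
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    combination: str = "all_four"

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.combination not in ("all_four", "any_one"):
            raise ValueError("combination must be 'all_four' or 'any_one'")
        if min(self.ror_ci_lower, self.prr_min, self.chi2_min, self.ebgm05_min) <= 0:
            raise ValueError("thresholds must be strictly positive")


def screen(scores: pd.DataFrame, policy: ThresholdPolicy = ThresholdPolicy()) -> pd.DataFrame:
    """Apply the threshold policy to a score table from ``disprop.score_tables``.

    Returns the scores with per-algorithm boolean verdicts (``sig_ror``,
    ``sig_prr``, ``sig_bcpnn``, ``sig_mgps``), an ``undefined`` column naming
    algorithms whose statistic could not be computed (their verdict is
    False), and the combined ``signal`` verdict. Terms below ``min_count``
    never appear in the output.
    """
    df = scores[scores["a"] >= policy.min_count].copy()

    checks = {
        "sig_ror": df["ror_lo"] > policy.ror_ci_lower,
        "sig_prr": (df["prr"] >= policy.prr_min) & (df["chi2"] >= policy.chi2_min),
        "sig_bcpnn": df["ic025"] > policy.ic025_min,
        "sig_mgps": df["ebgm05"] > policy.ebgm05_min,
    }
    undefined_src = {
        "sig_ror": ["ror_lo"],
        "sig_prr": ["prr", "chi2"],
        "sig_bcpnn": ["ic025"],
        "sig_mgps": ["ebgm05"],
    }
    undef_labels = pd.Series([[] for _ in range(len(df))], index=df.index, dtype=object)
    for name, verdict in checks.items():
        nan_mask = df[undefined_src[name]].isna().any(axis=1)
        df[name] = (verdict & ~nan_mask).astype(bool)
        for i in df.index[nan_mask]:
            undef_labels[i] = undef_labels[i] + [name.removeprefix("sig_")]
    df["undefined"] = undef_labels.apply(",".join)

    verdicts = df[list(checks)].to_numpy(dtype=bool)
    if policy.combination == "all_four":
        df["signal"] = verdicts.all(axis=1)
    else:
        df["signal"] = verdicts.any(axis=1)
    return df


def rank(
    flagged: pd.DataFrame, key: str = "report_count", top_k: int = 30
) -> pd.DataFrame:
    """Stable descending sort of flagged terms, truncated to ``top_k``.

    ``key`` is "report_count" (the a-cell) or "ebgm"; ties break on the other
    key, then on term name, so the order is deterministic across runs.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    cols = {"report_count": "a", "ebgm": "ebgm"}
    if key not in cols:
        raise ValueError(f"rank key must be one of {sorted(cols)}, got {key!r}")
    primary = cols[key]
    secondary = "ebgm" if primary == "a" else "a"
    out = flagged.sort_values(
        [primary, secondary, "term"], ascending=[False, False, True], kind="mergesort"
    )
    return out.head(top_k).reset_index(drop=True)
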