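import numpy as np
import pandas as pd
import pytest

from pvsignal.simulate import SimConfig, default_background, generate


def make_reports(rows: list[dict]) -> pd.DataFrame:
    """Build a harmonised-schema report frame from sparse row dicts."""
    defaults = {
        "primaryid": "1", "caseid": "1", "fda_dt": 20230101.0,
        "event_dt": "", "event_dt_key": np.nan, "event_dt_precision": 0,
        "event_date": pd.NaT, "sex": "unknown", "age_years": np.nan,
        "age_group": "unknown", "reporter": "unknown", "country": "",
        "outcomes": "", "serious": False,
    }
    if not rows:
        return pd.DataFrame(columns=list(defaults)).astype({"age_years": float})
    filled = [{**defaults, **row} for row in rows]
    df = pd.DataFrame(filled)
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal database shared across read-only tests."""
    bg = default_background(30)
    config = SimConfig(
        n_reports=4000, drug_share=0.15, background_pts=bg,
        planted_signals=[("Pt 020", 8.0)], seed=11,
    )
    tables, truth = generate(config)
    return config, tables, truth


@pytest.fixture()
def pt_soc_map(small_sim):
    config, _, _ = small_sim
    return {pt: soc for pt, soc, _ in config.background_pts}
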