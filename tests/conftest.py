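import numpy as np
import pandas as pd
import pytest

from glycotherm import (RatkowskyParams, ReactorConfig, SensitivitySpec,
                        load_packaged_model)
from glycotherm.scenarios import MEASURED_METABOLITES, run_round


@pytest.fixture(scope="session")
def model():
    return load_packaged_model()


@pytest.fixture(scope="session")
def params():
    return RatkowskyParams()


@pytest.fixture(scope="session")
def chemostat_config():
    return ReactorConfig(mode="chemostat")


@pytest.fixture(scope="session")
def batch_config():
    return ReactorConfig(mode="batch", evaporation_k=0.0)


@pytest.fixture(scope="session")
def round2_samples(model, params, chemostat_config):
    """Identical-sensitivity round over SBR + LTS30 + CTC (noise-free)."""
    return run_round(model, "identical", params, chemostat_config)


@pytest.fixture(scope="session")
def round1_tdhl_samples(model, params, chemostat_config):
    """Round with the TDH-lump two-fold less temperature-sensitive."""
    return run_round(model, "single_enzyme_different", params, chemostat_config,
                     sensitivity=SensitivitySpec("TDHL", 2.0))


def long_format(samples: pd.DataFrame) -> pd.DataFrame:
    """Wide scenario samples → tidy MeasurementTable-shaped rows (no noise)."""
    rows = []
    for _, r in samples.iterrows():
        for met in MEASURED_METABOLITES:
            rows.append({"regime": r["regime"], "time_h": r["time_h"],
                         "temperature_C": r["temperature_C"],
                         "glucose_mM": r["glucose_mM"], "metabolite": met,
                         "level": r[met], "sem": 0.0, "n": 1})
    return pd.DataFrame(rows)


def matched_position_spread(samples: pd.DataFrame, metabolite: str) -> float:
    """Worst relative spread across batch temperatures at matched sampling
    positions (same glucose fraction of the feed)."""
    sbr = samples[samples["regime"].str.startswith("SBR")]
    worst = 0.0
    for idx in sbr["sample_index"].unique():
        vals = sbr[sbr["sample_index"] == idx][metabolite]
        worst = max(worst, float(vals.max() / vals.min()) - 1.0)
    return worst
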