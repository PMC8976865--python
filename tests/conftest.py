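import logging

import numpy as np
import pandas as pd
import pytest

from nirsdual.sim import ScenarioConfig, simulate_recording, simulate_scores

logging.getLogger("nirsdual").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_cfg() -> ScenarioConfig:
    """Small but filterable scenario: sessions of 4 x 60 s + gaps = 270 s."""
    return ScenarioConfig(seed=42, n_subjects=4, subareas_per_session=4,
                          subarea_duration=60.0)


@pytest.fixture(scope="session")
def study_cfg() -> ScenarioConfig:
    """Full 13-subject study layout (used where n matters)."""
    return ScenarioConfig(seed=7)


@pytest.fixture(scope="session")
def scores_df(study_cfg) -> pd.DataFrame:
    return simulate_scores(study_cfg)


@pytest.fixture(scope="session")
def model_frame(scores_df) -> pd.DataFrame:
    """Score table in modeling layout (ID/Group/Session/AdpTF/Short)."""
    df = scores_df.rename(columns={"subject": "ID", "group": "Group",
                                   "session": "Session", "adp_tf": "AdpTF"})
    rng = np.random.default_rng(123)
    df = df.copy()
    df["Short"] = rng.standard_normal(len(df))
    return df


@pytest.fixture(scope="session")
def noisefree_recording(tiny_cfg):
    return simulate_recording(tiny_cfg, "S01", "E1", noise_free=True)


@pytest.fixture(scope="session")
def noisy_recording(tiny_cfg):
    return simulate_recording(tiny_cfg, "S01", "E1")
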