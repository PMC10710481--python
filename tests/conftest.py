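"""Shared fixtures: one small synthetic session reused across test modules."""

import numpy as np
import pytest

from replaykit import AnalysisConfig, SyntheticConfig, simulate_session


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        seed=7,
        n_cells_per_track=30,
        n_laps_t1=4,
        n_laps_t2=2,
        sleep_duration_s=600.0,
        run2_duration_s=200.0,
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    session, truth = simulate_session(small_cfg)
    return session, truth


@pytest.fixture(scope="session")
def analysis_cfg() -> AnalysisConfig:
    return AnalysisConfig(seed=3)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
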