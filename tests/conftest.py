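import numpy as np
import pytest

from estrocycle.params import (
    CellCycleParams,
    SignalingParams,
    COMPLETE_MEDIUM_E2,
)
from estrocycle.signaling import STATE_VARS, steady_state
from estrocycle.synth import SynthConfig, gen_fucci_tracks

#: founder cycle offsets scripted so that no phase boundary falls within the
#: smoothing half-window of the movie edges (keeps the recovered boundaries
#: comparable to the script everywhere in the 96-frame window)
ORACLE_OFFSETS = (20, 40, 56, 70, 85, 48)


@pytest.fixture(scope="session")
def sig_params() -> SignalingParams:
    return SignalingParams()


@pytest.fixture(scope="session")
def cyc_params() -> CellCycleParams:
    return CellCycleParams.default()


@pytest.fixture(scope="session")
def culture_state(sig_params) -> dict:
    """Model III steady state under the complete-medium E2 clamp."""
    ss = steady_state("III", sig_params, COMPLETE_MEDIUM_E2)
    return dict(zip(STATE_VARS["III"], ss))


@pytest.fixture(scope="session")
def fucci_oracle():
    """Noiseless scripted FUCCI movie with per-sample ground truth."""
    cfg = SynthConfig(seed=5, n_founders=len(ORACLE_OFFSETS), fucci_noise_sigma=0.0)
    tracks, truth = gen_fucci_tracks(cfg, founder_offsets=ORACLE_OFFSETS)
    return cfg, tracks, truth
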