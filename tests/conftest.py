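import numpy as np
import pandas as pd
import pytest

from pupilstress import ArtifactParams, StudyConfig
from pupilstress.pupil import TrialTrace

DT_MS = 1000.0 / 30.0


@pytest.fixture
def clean_config():
    """Tiny study, sample noise but no blink/spike artifacts."""
    return StudyConfig(n_per_cell=2, seed=7)


@pytest.fixture
def noiseless_config():
    """Tiny study with a fully deterministic pupil signal."""
    return StudyConfig(n_per_cell=2, seed=7, artifact_params=ArtifactParams.clean())


def make_trace(values, t0_ms=-300.0, dt_ms=DT_MS, condition="view_negative", trial=1):
    values = np.asarray(values, dtype=float)
    t = t0_ms + dt_ms * np.arange(values.size)
    return TrialTrace(trial=trial, condition=condition, t_ms=t, diameter_mm=values)


@pytest.fixture
def flat_trace():
    """160 samples at 30 Hz spanning -300 ms .. ~5000 ms, constant 4 mm."""
    return make_trace(np.full(160, 4.0))


@pytest.fixture
def events_one_trial():
    return pd.DataFrame(
        [{"participant": "P001", "trial": 1, "condition": "view_negative",
          "cue_ms": 0.0, "fix_ms": 750.0, "pic_ms": 3250.0}]
    )
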