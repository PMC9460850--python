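import numpy as np
import pytest

from respstage import SleepStage, default_stage_models, synth_epoch


@pytest.fixture(scope="session")
def models():
    return default_stage_models()


@pytest.fixture(scope="session")
def awake_zero(models):
    """Awake-stage model with all dispersion switched off."""
    return models[SleepStage.AWAKE].zero_variance()


@pytest.fixture(scope="session")
def awake_epoch_120s(awake_zero):
    """Noiseless 120-s awake epoch at the 0.272 Hz dominant frequency."""
    return synth_epoch(awake_zero, duration=120.0, dt=0.017, seed=0)


def count_cycles(trace, threshold_frac=0.5):
    """Independent breath counter: threshold upward crossings."""
    x = trace.samples
    thr = threshold_frac * x.max()
    above = x > thr
    return int(np.sum(~above[:-1] & above[1:]))
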