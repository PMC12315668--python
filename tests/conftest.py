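import numpy as np
import pytest

from clpnet.cohort import GeneratorConfig, default_config, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default cohort shared by read-only tests."""
    return simulate_cohort(default_config(400, seed=123))


@pytest.fixture(scope="session")
def shift_free_config():
    """Default dynamics but no group shifts / wave trends / attrition,
    so latent regressions identify the lag matrix exactly."""
    cfg = GeneratorConfig(target_attrition=0.0,
                          risk_mean_shift=np.zeros((5, 3)))
    cfg.measurement.wave_trends = np.zeros((5, 3))
    return cfg
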