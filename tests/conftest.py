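import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biomusic as bm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 256.0


@pytest.fixture(scope="session")
def cfg() -> bm.SonifyConfig:
    return bm.SonifyConfig()


@pytest.fixture(scope="session")
def relaxed_session():
    """One 300-s typically-developing relaxed session plus ground truth."""
    return bm.generate_session("td_anagram_relaxed", 300.0, FS, seed=11)


@pytest.fixture(scope="session")
def exp1_cohort():
    """Five synthetic typically-developing children, full acquisition timeline."""
    return bm.build_cohort("exp1", seed=42)


def constant_features(duration_s: float = 80.0, eda_us: float = 1.131,
                      temp_c: float = 32.0, ibi_s: float = 1.0):
    """Constant feature set used by the hand-simulated scheduling examples."""
    n_eda = int(duration_s / 0.25)
    feats = {
        "eda_level": bm.FeatureSeries("eda_level", np.arange(n_eda) * 0.25, np.full(n_eda, eda_us)),
        "temp_sample": bm.FeatureSeries("temp_sample", np.arange(duration_s), np.full(int(duration_s), temp_c)),
        "ibi": bm.FeatureSeries("ibi", 4.0 + np.arange(duration_s - 4), np.full(int(duration_s - 4), ibi_s)),
    }
    return feats
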