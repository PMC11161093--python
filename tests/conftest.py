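import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import phenofreeze as pf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_session(bins, animal_id="A1", sex="female", session="MR1"):
    return pf.FreezingSession(animal_id=animal_id, sex=sex, session=session,
                              bins=tuple(bins))


def decay_session(y0, b, baseline=5.0, animal_id="A1", sex="female", session="MR1"):
    """A noiseless session whose CS window follows y0*exp(-b t)."""
    t = np.arange(12.0)
    cs = y0 * np.exp(-b * t)
    return make_session([baseline] * 12 + list(cs), animal_id=animal_id,
                        sex=sex, session=session)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small noisy cohort with ground truth, shared across tests."""
    cfg = pf.SyntheticConfig(n_per_sex=12, seed=42)
    sessions_df, metrics_df, truth_df = pf.generate_cohort(cfg)
    return pf.frame_to_sessions(sessions_df), metrics_df, truth_df


@pytest.fixture(scope="session")
def mr1_features(noisy_cohort):
    sessions, _, _ = noisy_cohort
    fits = pf.fit_cohort([s for s in sessions if s.session == "MR1"])
    return pf.build_features(fits)
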