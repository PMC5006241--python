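import numpy as np
import pandas as pd
import pytest

from flickertime import DesignConfig, EffectParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Tiny experiment-1 design: 2 participants, 1 session, 2 reps/cell."""
    return DesignConfig(
        experiment=1, n_participants=2, n_sessions=1, reps_per_cell=2, seed=7
    )


@pytest.fixture
def exp2_cfg():
    return DesignConfig.for_experiment(2, seed=11)


def make_params(participants=("P01", "P02"), durations=(450, 650, 850),
                beta_mu=None, beta_sigma=None, u_mu=0.0, u_sigma=0.0,
                weber=0.15):
    """Hand-buildable EffectParams for small fixtures."""
    beta_mu = beta_mu or {"SS": 1.0, "FS": 1.2, "SFi": 1.1, "SFc": 1.05}
    beta_sigma = beta_sigma or dict(beta_mu)
    return EffectParams(
        beta_mu=dict(beta_mu),
        beta_sigma=dict(beta_sigma),
        gamma_mu={d: float(d) for d in durations},
        gamma_sigma={d: weber * d for d in durations},
        u_mu={p: u_mu for p in participants},
        u_sigma={p: u_sigma for p in participants},
        tau_mu=60.0,
        tau_sigma=15.0,
    )


@pytest.fixture
def flat_params():
    """Params with all random effects zero (cell mean = gamma_mu[d])."""
    return make_params()


def make_trials(rows):
    """Trial table from (participant, condition, duration, reproduced)."""
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "target_duration_ms",
                       "reproduced_ms"]
    )
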