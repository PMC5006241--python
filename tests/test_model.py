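"""Likelihood, priors and posterior of the location-scale model."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from flickertime import (
    DurationModel,
    EffectParams,
    log_likelihood,
    log_posterior,
    log_prior,
)

from conftest import make_params, make_trials


@pytest.fixture
def params():
    return make_params()


@pytest.fixture
def small_trials():
    return make_trials(
        [
            ("P01", "SS", 450, 430.0),
            ("P01", "FS", 450, 560.0),
            ("P01", "SFi", 650, 700.0),
            ("P02", "SS", 850, 820.0),
            ("P02", "SFc", 650, 640.0),
            ("P02", "FS", 850, 1100.0),
        ]
    )


class TestLogLikelihood:
    def test_single_trial_at_the_mode(self):
        # x = cell mean, cell sd = 100 -> density -log(100 sqrt(2 pi))
        params = make_params()
        params.gamma_sigma = {450: 100.0, 650: 100.0, 850: 100.0}
        trials = make_trials([("P01", "SS", 650, 650.0)])
        assert log_likelihood(params, trials) == pytest.approx(
            -math.log(100 * math.sqrt(2 * math.pi))
        )

    def test_additivity_over_trials(self, params, small_trials):
        total = log_likelihood(params, small_trials)
        parts = sum(
            log_likelihood(params, small_trials.iloc[[i]])
            for i in range(len(small_trials))
        )
        assert total == pytest.approx(parts)

    def test_reference_condition_constraint_enforced(self):
        with pytest.raises(ValueError, match="beta_mu\\[SS\\]"):
            make_params(beta_mu={"SS": 1.05, "FS": 1.2, "SFi": 1.1, "SFc": 1.05})

    def test_nonpositive_cell_sd_raises_naming_cell(self, small_trials):
        params = make_params(u_sigma=-200.0)
        with pytest.raises(ValueError, match="condition="):
            log_likelihood(params, small_trials)

    @given(perm=st.permutations(list(range(6))))
    @settings(deadline=None, max_examples=20)
    def test_invariant_to_trial_order(self, perm):
        params = make_params()
        trials = make_trials(
            [
                ("P01", "SS", 450, 430.0),
                ("P01", "FS", 450, 560.0),
                ("P01", "SFi", 650, 700.0),
                ("P02", "SS", 850, 820.0),
                ("P02", "SFc", 650, 640.0),
                ("P02", "FS", 850, 1100.0),
            ]
        )
        shuffled = trials.iloc[perm].reset_index(drop=True)
        assert log_likelihood(params, shuffled) == pytest.approx(
            log_likelihood(params, trials)
        )

    @given(k=st.floats(min_value=0.2, max_value=5.0))
    @settings(deadline=None, max_examples=25)
    def test_location_scale_family_property(self, k):
        # scaling data and all ms-scale params by k shifts loglik by -n log k
        params = make_params(u_mu=30.0, u_sigma=10.0)
        trials = make_trials(
            [
                ("P01", "SS", 450, 430.0),
                ("P01", "FS", 650, 800.0),
                ("P02", "SFi", 850, 900.0),
            ]
        )
        base = log_likelihood(params, trials)
        scaled = make_params(u_mu=30.0 * k, u_sigma=10.0 * k)
        scaled.gamma_mu = {d: k * v for d, v in params.gamma_mu.items()}
        scaled.gamma_sigma = {d: k * v for d, v in params.gamma_sigma.items()}
        scaled_trials = trials.assign(reproduced_ms=trials.reproduced_ms * k)
        assert log_likelihood(scaled, scaled_trials) == pytest.approx(
            base - len(trials) * math.log(k)
        )


class TestLogPrior:
    def test_nonpositive_multiplier_is_outside_support(self):
        params = make_params()
        params.beta_sigma["FS"] = -0.5
        assert log_prior(params) == -math.inf

    def test_longhand_component_sum(self):
        params = make_params(u_mu=0.0, u_sigma=0.0)
        expected = 0.0
        trunc = stats.truncnorm(a=-2.0, b=np.inf, loc=1.0, scale=0.5)
        for c in ("FS", "SFi", "SFc"):
            expected += trunc.logpdf(params.beta_mu[c])
            expected += trunc.logpdf(params.beta_sigma[c])
        for d in (450, 650, 850):
            expected += stats.norm.logpdf(params.gamma_mu[d], loc=d, scale=300)
            expected += stats.halfnorm.logpdf(params.gamma_sigma[d], scale=300)
        for _ in params.u_mu:
            expected += stats.norm.logpdf(0.0, scale=params.tau_mu)
            expected += stats.norm.logpdf(0.0, scale=params.tau_sigma)
        expected += stats.halfcauchy.logpdf(params.tau_mu, scale=100)
        expected += stats.halfcauchy.logpdf(params.tau_sigma, scale=100)
        assert log_prior(params) == pytest.approx(expected)

    def test_extra_participants_add_their_own_terms(self):
        two = make_params(participants=("P01", "P02"))
        four = make_params(participants=("P01", "P02", "P03", "P04"))
        extra = 2 * (
            stats.norm.logpdf(0.0, scale=two.tau_mu)
            + stats.norm.logpdf(0.0, scale=two.tau_sigma)
        )
        assert log_prior(four) == pytest.approx(log_prior(two) + extra)


class TestLogPosterior:
    def test_prior_support_violation_propagates(self, small_trials):
        params = make_params()
        params.tau_mu = -1.0
        assert log_posterior(params, small_trials) == -math.inf

    def test_equals_sum_of_components(self, params, small_trials):
        assert log_posterior(params, small_trials) == pytest.approx(
            log_likelihood(params, small_trials) + log_prior(params)
        )

    def test_likelihood_support_violation_propagates(self, small_trials):
        params = make_params(u_sigma=-200.0)
        assert log_posterior(params, small_trials) == -math.inf


class TestFastPathAgreement:
    """The sufficient-statistic path used by the sampler must agree with
    the row-by-row scipy reference implementation."""

    def test_loglike_and_prior_match_reference(self, small_trials):
        params = make_params(u_mu=25.0, u_sigma=5.0)
        model = DurationModel(small_trials)
        x = model.layout.pack(params)
        assert model.loglike_vec(x) == pytest.approx(
            log_likelihood(params, small_trials)
        )
        assert model.logprior_vec(x) == pytest.approx(log_prior(params))
        assert model.logpost_vec(x) == pytest.approx(
            log_posterior(params, small_trials)
        )

    def test_pack_unpack_roundtrip(self, small_trials):
        params = make_params(u_mu=25.0, u_sigma=5.0)
        model = DurationModel(small_trials)
        back = model.layout.unpack(model.layout.pack(params))
        assert back.to_flat_dict() == pytest.approx(params.to_flat_dict())

    def test_unconstrained_transform_roundtrip(self, small_trials):
        model = DurationModel(small_trials)
        x = model.layout.pack(make_params())
        z = model.layout.to_unconstrained(x)
        assert model.layout.to_natural(z) == pytest.approx(x)

    def test_empty_or_malformed_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            DurationModel(make_trials([]))
        with pytest.raises(KeyError, match="missing columns"):
            DurationModel(pd.DataFrame({"condition": ["SS"]}))
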