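"""Posterior summaries, comparison tests, recovery and fitted results."""
import numpy as np
import pandas as pd
import pytest

from flickertime import (
    DesignConfig,
    DurationModel,
    apply_gaze_exclusion,
    condition_ratio_tests,
    recovery_report,
    simulate_experiment,
    summarize_posterior,
)

from conftest import make_params


def draws_frame(**columns):
    df = pd.DataFrame(columns)
    n = len(df)
    df["chain"] = 1
    df["iteration"] = np.arange(1, n + 1)
    return df


class TestSummarizePosterior:
    def test_degenerate_draws_collapse_the_interval(self):
        s = summarize_posterior(draws_frame(**{"beta_mu.FS": [1.3] * 50}))
        row = s.loc["beta_mu.FS"]
        assert row["median"] == row["cri_low"] == row["cri_high"] == 1.3

    def test_median_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=101)
        s = summarize_posterior(draws_frame(p=vals))
        assert s.loc["p", "median"] == np.sort(vals)[50]

    def test_interval_excludes_extreme_five_percent_of_uniform(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(size=200_000)
        row = summarize_posterior(draws_frame(p=vals)).loc["p"]
        assert row.cri_low == pytest.approx(0.025, abs=0.005)
        assert row.cri_high == pytest.approx(0.975, abs=0.005)
        inside = ((vals >= row.cri_low) & (vals <= row.cri_high)).mean()
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_posterior(pd.DataFrame({"chain": [], "iteration": []}))


class TestConditionRatioTests:
    def beta_frame(self, fs, sfi, sfc):
        return draws_frame(
            **{"beta_mu.FS": fs, "beta_mu.SFi": sfi, "beta_mu.SFc": sfc}
        )

    def test_unanimous_draws_give_zero_p(self):
        n = 100
        s = self.beta_frame([1.3] * n, [1.2] * n, [1.1] * n)
        table = condition_ratio_tests(s).set_index("label")
        assert (table["raw_p"] == 0).all()
        assert (table["corrected_p"] == 0).all()
        assert (table["family_size"] == 6).all()

    def test_half_of_draws_above_one_gives_half_raw_p(self):
        fs = [0.9, 1.1] * 50
        s = self.beta_frame(fs, [1.2] * 100, [1.1] * 100)
        table = condition_ratio_tests(s).set_index("label")
        assert table.loc["FS_gt_1", "raw_p"] == 0.5
        assert table.loc["FS_gt_1", "corrected_p"] == 1.0

    def test_raw_p_equals_brute_force_count(self):
        rng = np.random.default_rng(11)
        fs = rng.normal(1.2, 0.05, 3000)
        sfi = rng.normal(1.1, 0.05, 3000)
        sfc = rng.normal(1.05, 0.05, 3000)
        table = condition_ratio_tests(self.beta_frame(fs, sfi, sfc)).set_index("label")
        assert table.loc["SFi_gt_SFc", "raw_p"] == np.sum(sfi <= sfc) / 3000
        assert table.loc["SFc_gt_1", "raw_p"] == np.sum(sfc <= 1.0) / 3000

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        fs = rng.normal(1.2, 0.1, 500)
        frame = self.beta_frame(fs, fs - 0.05, fs - 0.1)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            condition_ratio_tests(frame), condition_ratio_tests(shuffled)
        )

    def test_missing_condition_rejected(self):
        with pytest.raises(KeyError, match="beta_mu.SFc"):
            condition_ratio_tests(
                draws_frame(**{"beta_mu.FS": [1.2], "beta_mu.SFi": [1.1]})
            )


class TestRecoveryReport:
    def summary_from(self, params, widen=0.0, shift=0.0):
        flat = params.to_flat_dict()
        return pd.DataFrame(
            {
                "median": {k: v + shift for k, v in flat.items()},
                "cri_low": {k: v + shift - widen for k, v in flat.items()},
                "cri_high": {k: v + shift + widen for k, v in flat.items()},
            }
        ).rename_axis("parameter")

    def test_exact_estimates_give_zero_bias_full_coverage(self):
        params = make_params()
        rep = recovery_report(params, self.summary_from(params, widen=0.01))
        assert rep["mean_abs_bias_beta_mu"] == 0.0
        assert rep["coverage_fraction"] == 1.0

    def test_interval_missing_truth_flags_noncoverage(self):
        params = make_params()
        summary = self.summary_from(params, widen=0.05, shift=0.2)
        rep = recovery_report(params, summary)
        assert rep["coverage_fraction"] == 0.0
        fs = next(r for r in rep["parameters"] if r["parameter"] == "beta_mu.FS")
        assert fs["bias"] == pytest.approx(0.2)
        assert not fs["covered"]

    def test_name_mismatch_rejected(self):
        params = make_params()
        summary = self.summary_from(params).drop(index="beta_mu.SFc")
        with pytest.raises(KeyError, match="beta_mu.SFc"):
            recovery_report(params, summary)


@pytest.fixture(scope="module")
def fitted():
    """A small but real end-to-end fit (6 participants, 1 session)."""
    cfg = DesignConfig(experiment=1, n_participants=6, n_sessions=2,
                       reps_per_cell=8, seed=21)
    trials, truth = simulate_experiment(cfg)
    kept, _ = apply_gaze_exclusion(trials)
    res = DurationModel(kept).fit(n_chains=3, n_iter=1500, n_warmup=750, seed=22)
    return res, truth


class TestDurationResults:
    def test_pooled_draw_count_and_columns(self, fitted):
        res, _ = fitted
        assert len(res.samples) == 3 * 750
        assert {"chain", "iteration"} <= set(res.samples.columns)
        assert "beta_mu.FS" in res.samples.columns

    def test_ratios_recover_generating_truth(self, fitted):
        res, truth = fitted
        for cond in ("FS", "SFi", "SFc"):
            assert res.params[f"beta_mu.{cond}"] == pytest.approx(
                truth.beta_mu[cond], abs=0.06
            )

    def test_summary_text_mentions_ratios_and_comparisons(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "beta_mu.FS" in text
        assert "SFi_gt_SFc" in text
        assert "3 chains" in text

    def test_recovery_report_round_trip(self, fitted):
        res, truth = fitted
        rep = res.recovery(truth)
        assert 0.0 <= rep["coverage_fraction"] <= 1.0
        assert rep["mean_abs_bias_beta_mu"] < 0.06

    def test_dilation_ratio_rhat_near_unity(self, fitted):
        res, _ = fitted
        assert res.rhat().filter(like="beta_mu.").max() < 1.2

    def test_plot_returns_axis(self, fitted):
        import matplotlib
        matplotlib.use("Agg")
        res, _ = fitted
        ax = res.plot_condition_effects()
        assert len(ax.lines) >= 1

    def test_fit_determinism(self):
        cfg = DesignConfig(experiment=1, n_participants=2, n_sessions=1,
                           reps_per_cell=2, seed=3)
        trials, _ = simulate_experiment(cfg)
        r1 = DurationModel(trials).fit(n_chains=2, n_iter=200, n_warmup=100, seed=9)
        r2 = DurationModel(trials).fit(n_chains=2, n_iter=200, n_warmup=100, seed=9)
        pd.testing.assert_frame_equal(r1.samples, r2.samples)

    def test_every_pooled_draw_has_finite_log_posterior(self, fitted):
        res, _ = fitted
        model = res.model
        sub = res.samples.sample(n=50, random_state=0)
        for _, row in sub.iterrows():
            x = row[model.layout.names].to_numpy(dtype=float)
            assert np.isfinite(model.logpost_vec(x))


class TestAgainstEnsembleSampler:
    def test_medians_match_emcee_on_same_posterior(self):
        """Independent affine-invariant ensemble sampler (emcee) run on the
        identical log-posterior should give the same dilation-ratio
        medians up to Monte-Carlo error."""
        emcee = pytest.importorskip("emcee")
        cfg = DesignConfig(experiment=1, n_participants=4, n_sessions=2,
                           reps_per_cell=4, seed=31)
        trials, _ = simulate_experiment(cfg)
        model = DurationModel(trials)
        res = model.fit(n_chains=3, n_iter=2000, n_warmup=1000, seed=32)

        lay = model.layout
        z0 = lay.to_unconstrained(lay.pack(model.start_params()))
        nwalkers = 2 * lay.dim + 2
        rng = np.random.default_rng(33)
        p0 = z0 + 0.05 * rng.standard_normal((nwalkers, lay.dim))
        sampler = emcee.EnsembleSampler(nwalkers, lay.dim, model.logpost_z)
        sampler.run_mcmc(p0, 4000, progress=False)
        flat = sampler.get_chain(discard=2000, flat=True)

        sf = res.summary_frame()
        for j, name in enumerate(lay.names):
            if not name.startswith("beta_mu."):
                continue
            ours = sf.loc[name, "median"]
            theirs = np.median(np.exp(flat[:, j]) if lay.positive[j] else flat[:, j])
            sd = res.samples[name].std()
            # both medians carry Monte-Carlo error of a fair fraction of
            # the posterior SD (the ensemble sampler's autocorrelation
            # time is several hundred steps here)
            assert abs(ours - theirs) < 0.6 * sd + 0.005
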