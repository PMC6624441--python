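"""Tests for the Gibbs/slice sampler, R-hat and posterior summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hblater import (
    GroupParameters,
    ModelConfig,
    PersonEffects,
    SamplerConfig,
    joint_log_posterior,
    make_recovery_fixture,
    rhat,
    sample_posterior,
    summarize,
    summary_table,
)
from hblater.inference import (
    PosteriorDraws,
    _data_log_density_suffstats,
    _suffstats,
    sample_accretion_fixed_caution,
)
from hblater.model import compose_trial_accretion, compose_trial_caution, trial_log_density


class TestRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 10_000))
        assert 0.99 <= rhat(chains) <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert rhat(chains) > 1.1

    def test_identical_chains_match_direct_formula(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=1000)
        chains = np.stack([base, base])
        # evaluate the split-chain formula directly on the four halves
        split = np.stack([base[:500], base[500:], base[:500], base[500:]])
        W = split.var(axis=1, ddof=1).mean()
        B_over_n = split.mean(axis=1).var(ddof=1)
        expected = np.sqrt((499 / 500 * W + B_over_n) / W)
        assert rhat(chains) == pytest.approx(float(expected), abs=1e-12)

    def test_agrees_with_arviz_split_variant(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        for n in (500, 501):
            chains = rng.normal(size=(4, n)) + rng.normal(size=(4, 1)) * 0.3
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = float(
                    az.rhat(az.convert_to_dataset(chains), method="split")["x"].values
                )
            assert rhat(chains) == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_returns_sentinel_with_warning(self):
        chains = np.full((2, 100), 3.0)
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            assert np.isnan(rhat(chains))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            rhat(np.zeros((2, 3)))


def _draws_from_array(arr, name="x"):
    arr = np.asarray(arr, dtype=float)
    cfg = SamplerConfig(n_chains=arr.shape[0], n_iterations=arr.shape[1], n_burnin=0)
    return PosteriorDraws(
        samples=arr[:, :, None],
        names=[name],
        config=cfg,
        model_config=ModelConfig(),
        person_ids=[],
        covariate_names=[],
    )


class TestSummarize:
    def test_small_hand_case(self):
        d = _draws_from_array([[1.0, 2.0], [3.0, 4.0]])
        s = summarize(d, "x")
        assert s.mean == 2.5

    def test_constant_draws(self):
        d = _draws_from_array(np.full((2, 50), 7.0))
        s = summarize(d, "x")
        assert (s.mean, s.sd) == (7.0, 0.0)
        assert (s.ci_lower, s.ci_upper) == (7.0, 7.0)

    def test_gaussian_quantile_oracle(self):
        rng = np.random.default_rng(4)
        d = _draws_from_array(rng.normal(size=(2, 50_000)))
        s = summarize(d, "x")
        assert s.ci_lower == pytest.approx(-1.96, abs=0.03)
        assert s.ci_upper == pytest.approx(1.96, abs=0.03)
        assert s.ci_lower <= s.mean <= s.ci_upper

    def test_unknown_parameter_lists_candidates(self):
        d = _draws_from_array(np.zeros((2, 10)))
        with pytest.raises(KeyError, match="x"):
            summarize(d, "not_a_parameter")


class TestSufficientStatistics:
    @pytest.mark.parametrize("form", ["direct", "reciprocal"])
    def test_data_term_matches_per_trial_evaluation(self, form):
        prepared, truth = make_recovery_fixture(seed=9, n_persons=4, trials_per_cell=25)
        N, S1, S2 = _suffstats(prepared, form)
        v = truth.effects.v
        th = truth.effects.theta
        dv, dth = truth.group.delta_v, truth.group.delta_theta
        got = _data_log_density_suffstats(
            N, S1, S2, v, th, dv, dth, form, rt=prepared.rt
        )
        v_n = compose_trial_accretion(v[prepared.person_idx], prepared.G, dv)
        th_n = compose_trial_caution(th[prepared.person_idx], prepared.G, dth)
        direct = float(np.sum(trial_log_density(prepared.rt, v_n, th_n, form)))
        assert got == pytest.approx(direct, rel=1e-12)


class TestSamplePosterior:
    def test_same_seed_reproduces_bitwise(self):
        prepared, _ = make_recovery_fixture(seed=2, n_persons=3, trials_per_cell=20)
        cfg = SamplerConfig(n_chains=2, n_iterations=80, n_burnin=40, seed=13)
        a = sample_posterior(prepared, ModelConfig(), cfg)
        b = sample_posterior(prepared, ModelConfig(), cfg)
        assert np.array_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(summary_table(a), summary_table(b))

    def test_every_declared_parameter_is_sampled(self, small_fit):
        prepared, _, draws = small_fit
        names = set(draws.names)
        for c in ("1", "2", "3"):
            assert f"delta_v[{c}]" in names and f"delta_theta[{c}]" in names
        for p in prepared.person_ids:
            assert f"v[{p}]" in names and f"theta[{p}]" in names
        assert {"sigma_v", "sigma_theta"} <= names
        assert draws.n_retained == 150

    def test_empty_or_single_person_rejected(self):
        prepared, _ = make_recovery_fixture(seed=2, n_persons=3, trials_per_cell=10)
        prepared.rt = prepared.rt[:0]
        prepared.person_idx = prepared.person_idx[:0]
        prepared.cond_idx = prepared.cond_idx[:0]
        prepared.G = prepared.G[:0]
        with pytest.raises(ValueError, match="empty"):
            sample_posterior(prepared, ModelConfig(), SamplerConfig(seed=0))
        import pandas as pd

        from hblater import prepare_dataset

        trials = pd.DataFrame(
            {
                "person_id": "only",
                "session": "smoke_as_usual",
                "trial_type": ["neutral"] * 5 + ["reward"] * 5,
                "rt": 0.3,
            }
        )
        single = prepare_dataset(trials)
        with pytest.raises(ValueError, match="2 persons"):
            sample_posterior(single, ModelConfig(), SamplerConfig(seed=0))

    def test_burnin_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=1)


class TestConjugateReduction:
    def test_single_person_fixed_caution_matches_closed_form(self):
        # with caution fixed, w = theta*y ~ N(v, 1) and a Gaussian prior on v
        # is conjugate: posterior N((sum w + m0/s0^2)/(n + 1/s0^2), 1/(n + 1/s0^2))
        rng = np.random.default_rng(31)
        theta, v_true = 10.0, 3.0
        y = rng.normal(v_true / theta, 1.0 / theta, size=400)
        y = y[y > 0]  # the likelihood is evaluated on positive latencies
        m0, s0 = 0.0, 10.0
        draws = sample_accretion_fixed_caution(
            y, theta, m0, s0, n_draws=6000, seed=17
        )
        prec = y.size + 1.0 / s0**2
        post_mean = (theta * y.sum() + m0 / s0**2) / prec
        post_sd = 1.0 / np.sqrt(prec)
        az = pytest.importorskip("arviz")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(draws[None, :]))
        mcse_mean = post_sd / np.sqrt(ess)
        mcse_sd = post_sd / np.sqrt(2 * ess)
        assert draws.mean() == pytest.approx(post_mean, abs=3 * mcse_mean)
        assert draws.std(ddof=1) == pytest.approx(post_sd, abs=3 * mcse_sd)


class TestHierarchicalRecoveryProperties:
    def test_credible_interval_coverage_of_condition_effects(self):
        """95% CrIs for the six condition deviations cover truth >= 80% of
        the time across 20 seeded replications (reduced problem size)."""
        n_rep, covered, total = 20, 0, 0
        for rep in range(n_rep):
            prepared, truth = make_recovery_fixture(
                seed=100 + rep, n_persons=12, trials_per_cell=100
            )
            draws = sample_posterior(
                prepared,
                ModelConfig(),
                SamplerConfig(n_chains=3, n_iterations=1000, n_burnin=500,
                              seed=200 + rep),
            )
            named = truth.named()
            for c in (1, 2, 3):
                for block in ("delta_v", "delta_theta"):
                    name = f"{block}[{c}]"
                    s = summarize(draws, name)
                    total += 1
                    covered += s.ci_lower <= named[name] <= s.ci_upper
        assert covered / total >= 0.80

    def test_shrinkage_toward_covariate_means_as_sigma_vanishes(self):
        """Smaller true accretion heterogeneity gives posterior-mean person
        accretion estimates that sit closer to the group mean (monotone over
        a 3-point sigma grid)."""
        spreads = []
        for i, sigma_v in enumerate((0.02, 0.15, 0.6)):
            group = GroupParameters(
                beta_v=np.array([3.0, 0, 0, 0, 0.0]),
                beta_theta=np.array([10.0, 0, 0, 0, 0.0]),
                sigma_v=sigma_v,
                sigma_theta=1.0,
                delta_v=np.array([-0.35, 0.12, -0.25]),
                delta_theta=np.array([-0.07, 0.08, 0.0]),
            )
            prepared, truth = make_recovery_fixture(
                seed=55, n_persons=10, trials_per_cell=80, group=group
            )
            draws = sample_posterior(
                prepared,
                ModelConfig(),
                SamplerConfig(n_chains=2, n_iterations=600, n_burnin=300, seed=66),
            )
            v_means = np.array(
                [summarize(draws, f"v[{p}]").mean for p in prepared.person_ids]
            )
            spreads.append(float(np.std(v_means)))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_more_trials_tighten_person_effect_posteriors(self):
        """Average posterior SD of person effects strictly decreases when the
        per-person trial count grows 50 -> 500."""
        sds = []
        for trials_per_cell in (13, 125):  # ~50 and 500 trials per person
            prepared, _ = make_recovery_fixture(
                seed=77, n_persons=8, trials_per_cell=trials_per_cell
            )
            draws = sample_posterior(
                prepared,
                ModelConfig(),
                SamplerConfig(n_chains=2, n_iterations=600, n_burnin=300, seed=88),
            )
            person_sds = [
                summarize(draws, f"{blk}[{p}]").sd
                for p in prepared.person_ids
                for blk in ("v", "theta")
            ]
            sds.append(float(np.mean(person_sds)))
        assert sds[1] < sds[0]


class TestJointPosteriorConsistency:
    def test_posterior_draws_have_finite_joint_density(self, small_fit):
        prepared, _, draws = small_fit
        # spot-check a few retained draws against the exact joint density
        P = len(prepared.person_ids)
        for d in (0, draws.n_retained // 2, draws.n_retained - 1):
            vec = {n: draws.samples[0, d, i] for i, n in enumerate(draws.names)}
            group = GroupParameters(
                beta_v=[vec[f"beta_v[{c}]"] for c in prepared.covariate_names],
                beta_theta=[vec[f"beta_theta[{c}]"] for c in prepared.covariate_names],
                sigma_v=vec["sigma_v"],
                sigma_theta=vec["sigma_theta"],
                delta_v=[vec[f"delta_v[{c}]"] for c in (1, 2, 3)],
                delta_theta=[vec[f"delta_theta[{c}]"] for c in (1, 2, 3)],
            )
            effects = PersonEffects(
                v=[vec[f"v[{p}]"] for p in prepared.person_ids],
                theta=[vec[f"theta[{p}]"] for p in prepared.person_ids],
            )
            lp = joint_log_posterior(prepared, group, effects, ModelConfig())
            assert np.isfinite(lp)
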