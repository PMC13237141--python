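import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from loopbelief import (
    AttributionPolicy,
    CohortSpec,
    TaskConfig,
    bh_fdr,
    expectation_lmm,
    external_attribution_model,
    frame_to_records,
    generate_dataset,
    learning_bias,
    one_sample_t,
    posterior_predictive_check,
    sample_cohort,
    spearman_with_fdr,
    wilcoxon_signed,
    within_between_decompose,
)


class TestLearningBias:
    def test_equal_rates_give_zero(self):
        assert learning_bias(0.3, 0.3) == 0.0

    def test_reference_median_rates(self):
        # (0.11 - 0.24) / (0.11 + 0.24)
        assert learning_bias(0.11, 0.24) == pytest.approx(-0.371428, abs=1e-5)

    def test_boundaries(self):
        assert learning_bias(0.4, 0.0) == 1.0
        assert learning_bias(0.0, 0.4) == -1.0

    def test_antisymmetry(self):
        for a, b in [(0.1, 0.5), (0.33, 0.12)]:
            assert learning_bias(a, b) == pytest.approx(-learning_bias(b, a))

    def test_undefined_for_zero_rates(self):
        with pytest.raises(ValueError):
            learning_bias(0.0, 0.0)


class TestWilcoxonSigned:
    def test_exact_mode_matches_scipy_enumeration(self):
        # untied n=6 pairs: scipy's exact distribution is the 2^6 enumeration
        x = np.array([3.1, 1.2, 5.4, 2.2, 0.7, 4.9])
        y = np.array([2.0, 2.5, 1.1, 2.9, 0.1, 1.5])
        ours = wilcoxon_signed(x, y, exact=True)
        ref = stats.wilcoxon(x, y, mode="exact")
        assert ours.p_raw == pytest.approx(ref.pvalue)
        assert ours.extra["exact"] is True

    def test_small_n_defaults_to_exact(self):
        x = np.arange(8.0)
        y = x + np.array([1, -2, 3, -1, 2, 1, -1, 2.0])
        assert wilcoxon_signed(x, y).extra["exact"] is True

    def test_effect_size_is_z_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 1, 40)
        res = wilcoxon_signed(x, np.zeros(40))
        assert res.effect_size == pytest.approx(abs(res.statistic) / np.sqrt(res.n))

    def test_hodges_lehmann_shift_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1, 30)
        y = np.zeros(30)
        a = wilcoxon_signed(x, y)
        b = wilcoxon_signed(x + 2.5, y)
        assert b.extra["hodges_lehmann"] == pytest.approx(a.extra["hodges_lehmann"] + 2.5)
        assert b.ci_low == pytest.approx(a.ci_low + 2.5)
        assert b.ci_high == pytest.approx(a.ci_high + 2.5)

    def test_null_data_usually_nonsignificant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        res = wilcoxon_signed(x, np.zeros(200))
        assert res.p_raw > 0.05

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed(np.ones(10), np.ones(10))


class TestOneSampleT:
    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t(np.array([-1.0, -0.5, 0.5, 1.0]), 0.0)
        assert res.statistic == pytest.approx(0.0)

    def test_reference_attribution_weight_magnitudes(self):
        # mean 0.51, sd 0.17, n 64 -> t = 24.0, d = 3.0
        base = np.linspace(-1, 1, 64)
        base = (base - base.mean()) / base.std(ddof=1)
        v = 0.51 + 0.17 * base
        res = one_sample_t(v, 0.0)
        assert res.statistic == pytest.approx(24.0, abs=1e-10)
        assert res.effect_size == pytest.approx(3.0, abs=1e-10)
        assert res.ci_low < 3.0 < res.ci_high

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0.4, 0.2, 25)
        res = one_sample_t(v, 0.1)
        t_ref = (v.mean() - 0.1) / (v.std(ddof=1) / np.sqrt(25))
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p_raw == pytest.approx(stats.ttest_1samp(v, 0.1).pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(np.full(10, 0.3))


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_ties_stay_equal(self):
        out = bh_fdr([0.02, 0.02, 0.02])
        assert len(set(np.round(out, 12))) == 1

    def test_matches_statsmodels_step_up(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 37)
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    def test_adjusted_at_least_raw_and_order_invariant(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 20)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm])

    def test_grouping_adjusts_within_groups_only(self):
        p = [0.01, 0.02, 0.01, 0.02]
        groups = ["a", "a", "b", "b"]
        np.testing.assert_allclose(bh_fdr(p, groups), bh_fdr([0.01, 0.02]).tolist() * 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSpearman:
    def test_monotone_pair_gives_unit_rho(self):
        x = np.arange(10.0)
        res = spearman_with_fdr([(x, np.exp(x), "mono")])[0]
        assert res.statistic == pytest.approx(1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2, 2, 3, 5, 5, 7, 8])
        y = np.array([3.0, 1, 4, 4, 6, 5, 9, 8])
        res = spearman_with_fdr([(x, y, "ties")])[0]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert res.statistic == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_joint_adjustment_never_lowers_max_p(self):
        rng = np.random.default_rng(6)
        pairs = [(rng.normal(size=20), rng.normal(size=20), f"p{i}") for i in range(3)]
        results = spearman_with_fdr(pairs)
        assert max(r.p_adjusted for r in results) >= max(r.p_raw for r in results)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_fdr([(np.ones(10), np.arange(10.0), "const")])


class TestWithinBetween:
    def test_hand_example(self):
        w, b = within_between_decompose([10, 20, 30, 40], ["A", "A", "B", "B"])
        np.testing.assert_allclose(w, [-5, 5, -5, 5])
        np.testing.assert_allclose(b, [-10, -10, 10, 10])

    def test_constant_within_subject_gives_zero_within(self):
        w, _ = within_between_decompose([3, 3, 7, 7], ["A", "A", "B", "B"])
        np.testing.assert_allclose(w, 0.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=30)
        s = rng.integers(0, 5, size=30)
        w, b = within_between_decompose(v, s)
        np.testing.assert_allclose(w + b + v.mean(), v)
        for g in np.unique(s):
            assert w[s == g].sum() == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def cohort_dataset():
    cohort = sample_cohort(CohortSpec(n_subjects=16, seed=7))
    trials = generate_dataset(cohort, TaskConfig())
    traits = pd.Series({p.subject_id: float(p.sdq) for p in cohort})
    return cohort, trials, traits


class TestAttributionLmm:
    def test_self_serving_generator_recovers_negative_valence_effect(self, cohort_dataset):
        _, trials, traits = cohort_dataset
        m = external_attribution_model(trials, traits, "sdq")
        assert m.beta("valence") < 0  # worse-than-expected -> more external
        assert m.p("valence") < 0.05
        assert m.beta("extremity_within") > 0

    def test_trait_interaction_sign_recovered(self):
        pol = AttributionPolicy(b0=-0.5, b_neg=1.0, b_extremity=0.0,
                                b_trait=0.0, b_trait_x_neg=1.5)
        cohort = sample_cohort(CohortSpec(n_subjects=24, seed=13, policy=pol))
        trials = generate_dataset(cohort, TaskConfig())
        traits = pd.Series({p.subject_id: float(p.sdq) for p in cohort})
        m = external_attribution_model(trials, traits, "sdq")
        # higher trait -> more external after negative PEs -> negative interaction
        assert m.beta("valence:trait") < 0
        assert m.p("valence:trait") < 0.05

    def test_null_policy_shows_no_valence_effect(self):
        pol = AttributionPolicy(0, 0, 0, 0, 0)
        cohort = sample_cohort(CohortSpec(n_subjects=24, seed=13, policy=pol))
        trials = generate_dataset(cohort, TaskConfig())
        traits = pd.Series({p.subject_id: float(p.sdq) for p in cohort})
        m = external_attribution_model(trials, traits, "sdq")
        assert m.p("valence") > 0.05

    def test_missing_trait_scores_named(self, cohort_dataset):
        _, trials, traits = cohort_dataset
        with pytest.raises(ValueError, match="missing trait scores"):
            external_attribution_model(trials, traits.iloc[:-2], "sdq")


class TestExpectationLmm:
    def test_trial_by_ability_interaction_positive(self, cohort_dataset):
        _, trials, _ = cohort_dataset
        m = expectation_lmm(trials)
        # High-Ability expectations rise across trials, Low-Ability fall
        assert m.beta("trial_c:ability_c") > 0
        assert m.p("trial_c:ability_c") < 0.001
        assert m.beta("ability_c") > 0

    def test_duplicating_dataset_leaves_betas_unchanged(self, cohort_dataset):
        _, trials, _ = cohort_dataset
        m1 = expectation_lmm(trials)
        m2 = expectation_lmm(pd.concat([trials, trials], ignore_index=True))
        np.testing.assert_allclose(
            m2.effects["beta"].to_numpy(), m1.effects["beta"].to_numpy(), rtol=1e-3
        )


class TestPosteriorPredictive:
    def test_sign_pattern_matches_between_observed_and_predicted(self, cohort_dataset):
        cohort, trials, _ = cohort_dataset
        sessions = frame_to_records(trials)
        params = {p.subject_id: p.params for p in cohort}
        ppc = posterior_predictive_check(params, sessions)
        obs, pred = ppc["observed"], ppc["predicted"]
        for effect in ("trial_c:ability_c", "ability_c"):
            assert np.sign(obs.beta(effect)) == np.sign(pred.beta(effect))

    def test_predictions_fed_back_reproduce_their_own_fit(self, cohort_dataset):
        import dataclasses

        cohort, trials, _ = cohort_dataset
        sessions = frame_to_records(trials)
        params = {p.subject_id: p.params for p in cohort}
        from loopbelief import ModelId, simulate_trajectory
        from loopbelief.belief_models import group_by_condition

        # overwrite observed ratings with the model's noise-free predictions
        fed = {}
        for sid, session in sessions.items():
            trajs = simulate_trajectory(ModelId.M5_attribution_weighting, params[sid], session)
            new = []
            for rec in session:
                cid = rec.condition.category_id
                pos = [r.trial_within for r in group_by_condition(session)[cid]].index(rec.trial_within)
                e = float(trajs[cid].expectations[pos])
                new.append(dataclasses.replace(rec, expectation=e, realized_pe=rec.feedback - e))
            fed[sid] = new
        ppc = posterior_predictive_check(params, fed)
        np.testing.assert_allclose(
            ppc["observed"].effects["beta"].to_numpy(),
            ppc["predicted"].effects["beta"].to_numpy(),
            rtol=1e-6, atol=1e-8,
        )

    def test_no_learning_cohort_has_flat_predicted_trajectories(self):
        cohort = sample_cohort(CohortSpec(n_subjects=8, seed=9, sigma_range=(1.0, 1.0)))
        trials = generate_dataset(cohort, TaskConfig())
        sessions = frame_to_records(trials)
        # evaluate predictions under zero learning rates
        params = {
            p.subject_id: p.params.with_(alpha_pos=0.0, alpha_neg=0.0) for p in cohort
        }
        ppc = posterior_predictive_check(params, sessions)
        assert abs(ppc["predicted"].beta("trial_c")) < 1e-6
        assert abs(ppc["predicted"].beta("trial_c:ability_c")) < 1e-6

    def test_missing_fit_excluded_with_warning(self, cohort_dataset):
        cohort, trials, _ = cohort_dataset
        sessions = frame_to_records(trials)
        params = {p.subject_id: p.params for p in cohort[1:]}
        with pytest.warns(UserWarning, match="no fit for subject"):
            ppc = posterior_predictive_check(params, sessions)
        assert ppc["observed"].n_subjects == len(cohort) - 1
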