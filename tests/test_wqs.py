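"""Constrained WQS estimation, bootstrap averaging, validation model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import wqsses as w
from wqsses import assembly, scoring
from wqsses.wqs import BootstrapEstimate, WQSWeights, _resample_indices


def _training_arrays(study):
    comp = assembly.join_components(study.individuals, study.areas, study.spec)
    rules = scoring.fit_index_rules(comp, study.spec)
    q = scoring.score_index(comp, study.spec, rules)
    z = assembly.encode_covariates(study.individuals)
    z = z.loc[:, z.std() > 0]
    y = study.individuals["outcome"].to_numpy(dtype=float)
    return q.to_numpy(), z.to_numpy(), y


class TestAIC:
    def test_arithmetic(self):
        assert w.aic(-10.0, 3) == 26.0
        assert w.aic(-7.5, 0) == 15.0

    def test_manual_bernoulli_likelihood_six_rows(self):
        # tiny fixture: compute the log-likelihood by hand from fitted probs
        y = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        wqs_index = np.array([3.0, 0.0, 2.0, 3.0, 1.0, 2.0])
        z = np.empty((6, 0))
        fit = w.fit_validation(wqs_index, z, y)
        from scipy.special import expit
        p = expit(fit.beta0 + fit.beta1 * wqs_index)
        manual_ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert fit.loglik == pytest.approx(manual_ll, abs=1e-6)
        assert fit.k == 2
        assert fit.aic == pytest.approx(-2 * manual_ll + 4, abs=1e-6)


class TestFitConstrained:
    def test_single_component_degenerates_to_plain_logistic(self, small_study):
        q, z, y = _training_arrays(small_study)
        q1 = q[:, :1]
        est = w.fit_constrained(q1, z, y)
        np.testing.assert_allclose(est.w, [1.0])
        X = np.column_stack([np.ones(len(y)), q1[:, 0], z])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert est.beta0 == pytest.approx(ref.params[0], abs=1e-8)
        assert est.beta1 == pytest.approx(ref.params[1], abs=1e-8)
        np.testing.assert_allclose(est.phi, ref.params[2:], atol=1e-8)

    def test_simplex_constraint_holds(self, small_study):
        q, z, y = _training_arrays(small_study)
        est = w.fit_constrained(q, z, y)
        assert est.converged
        assert est.w.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(est.w >= -1e-9) and np.all(est.w <= 1 + 1e-9)

    def test_two_component_profile_grid_oracle(self):
        from wqsses.experiments import oracle_gap
        r = oracle_gap(seed=5, n=250)
        assert r["gap"] <= 1e-3

    def test_null_outcome_gives_null_t_statistics(self, small_study):
        # outcome independent of the components: |t| < 3 in most refits
        q, z, _ = _training_arrays(small_study)
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(10):
            y_null = rng.integers(0, 2, size=len(q)).astype(float)
            est = w.fit_constrained(q, z, y_null)
            hits += abs(est.t_stat) < 3
        assert hits >= 8


class TestBootstrap:
    def test_same_seed_identical_estimates(self, small_study):
        q, z, y = _training_arrays(small_study)
        a = w.bootstrap_weights(q, z, y, B=3, seed=5)
        b = w.bootstrap_weights(q, z, y, B=3, seed=5)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.w, eb.w)
            assert ea.t_stat == eb.t_stat

    def test_single_bootstrap_equals_direct_fit_on_its_resample(self, small_study):
        q, z, y = _training_arrays(small_study)
        ests = w.bootstrap_weights(q, z, y, B=1, seed=11)
        idx = _resample_indices(np.random.default_rng(11), len(y))
        direct = w.fit_constrained(q[idx], z[idx], y[idx])
        np.testing.assert_allclose(ests[0].w, direct.w, atol=1e-10)
        assert ests[0].loglik == pytest.approx(direct.loglik)

    def test_rejects_bad_B(self, small_study):
        q, z, y = _training_arrays(small_study)
        with pytest.raises(ValueError):
            w.bootstrap_weights(q, z, y, B=0, seed=0)


class TestAverageWeights:
    def _est(self, wvec, t, beta1=0.5, converged=True):
        wvec = np.asarray(wvec, dtype=float)
        return BootstrapEstimate(w=wvec, beta0=0.0, beta1=beta1,
                                 phi=np.empty(0), t_stat=t, loglik=-1.0,
                                 converged=converged)

    def test_identical_weights_unchanged(self):
        ests = [self._est([0.6, 0.4], 1.0), self._est([0.6, 0.4], 7.0)]
        avg = w.average_weights(ests)
        np.testing.assert_allclose(avg.w, [0.6, 0.4])

    def test_t_stat_weighted_mean(self):
        ests = [self._est([1.0, 0.0], 1.0), self._est([0.0, 1.0], 3.0)]
        avg = w.average_weights(ests)
        np.testing.assert_allclose(avg.w, [0.25, 0.75])

    def test_wrong_sign_bootstraps_excluded(self):
        ests = [self._est([1.0, 0.0], 2.0),
                self._est([0.0, 1.0], 5.0, beta1=-0.3)]
        avg = w.average_weights(ests)
        np.testing.assert_allclose(avg.w, [1.0, 0.0])
        assert avg.n_contributing == 1

    def test_fallback_when_no_positive_bootstraps(self):
        ests = [self._est([0.2, 0.8], 2.0, beta1=-0.1),
                self._est([0.4, 0.6], 2.0, beta1=-0.2)]
        avg = w.average_weights(ests)
        np.testing.assert_allclose(avg.w, [0.3, 0.7])

    @given(
        st.lists(
            st.tuples(
                st.lists(st.floats(min_value=0.001, max_value=1), min_size=3, max_size=3),
                st.floats(min_value=-10, max_value=10),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_output_always_on_simplex(self, raw):
        ests = [
            self._est(np.asarray(wv) / np.sum(wv), t, beta1=t)
            for wv, t in raw
        ]
        avg = w.average_weights(ests)
        assert avg.w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(avg.w >= 0) and np.all(avg.w <= 1)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            w.average_weights([])


class TestComputeWQS:
    def test_degenerate_weight_selects_column(self):
        weights = WQSWeights(components=["a", "b"], w=np.array([1.0, 0.0]))
        q = pd.DataFrame({"a": [3.0], "b": [2.0]})
        np.testing.assert_allclose(w.compute_wqs(q, weights), [3.0])

    def test_manual_dot_product(self):
        weights = WQSWeights(components=["a", "b"], w=np.array([0.25, 0.75]))
        q = pd.DataFrame({"a": [0.0, 2.0, 3.0], "b": [1.0, 1.0, 3.0]})
        np.testing.assert_allclose(w.compute_wqs(q, weights), [0.75, 1.25, 3.0])

    def test_quartile_index_bounded(self):
        weights = WQSWeights(components=list("abcd"), w=np.full(4, 0.25))
        rng = np.random.default_rng(0)
        q = pd.DataFrame(rng.integers(0, 4, size=(50, 4)), columns=list("abcd")).astype(float)
        idx = w.compute_wqs(q, weights)
        assert idx.min() >= 0 and idx.max() <= 3


class TestFitValidation:
    def test_wald_ci_closed_form(self, small_study):
        q, z, y = _training_arrays(small_study)
        weights = WQSWeights(components=[f"c{i}" for i in range(q.shape[1])],
                             w=np.full(q.shape[1], 1 / q.shape[1]))
        fit = w.fit_validation(q @ weights.w, z, y, weights=weights)
        assert fit.ci_low == pytest.approx(np.exp(fit.beta1 - 1.96 * fit.se_beta1))
        assert fit.ci_high == pytest.approx(np.exp(fit.beta1 + 1.96 * fit.se_beta1))
        assert fit.ci_low < fit.odds_ratio < fit.ci_high

    def test_null_index_or_near_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=2000).astype(float)
        idx = rng.integers(0, 4, size=2000).astype(float)
        fit = w.fit_validation(idx, np.empty((2000, 0)), y)
        assert fit.ci_low <= 1.0 <= fit.ci_high

    def test_aic_matches_statsmodels(self, small_study):
        q, z, y = _training_arrays(small_study)
        idx = q.mean(axis=1)
        fit = w.fit_validation(idx, z, y)
        X = np.column_stack([np.ones(len(y)), idx, z])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.aic == pytest.approx(ref.aic, rel=1e-9)


class TestEqualWeights:
    def test_eleven_components_weight_rounds_to_0_091(self):
        rng = np.random.default_rng(2)
        q = pd.DataFrame(rng.integers(0, 4, size=(200, 11)).astype(float),
                         columns=[f"v{i}" for i in range(11)])
        y = rng.integers(0, 2, size=200).astype(float)
        fit = w.fit_equal_weights(q, np.empty((200, 0)), y)
        assert np.all(np.round(fit.weights.w, 3) == 0.091)

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        q = pd.DataFrame(rng.integers(0, 4, size=(100, 5)).astype(float),
                         columns=list("abcde"))
        weights = WQSWeights(components=list("abcde"), w=np.full(5, 0.2))
        permuted = q[["d", "b", "e", "a", "c"]]
        wp = WQSWeights(components=["d", "b", "e", "a", "c"], w=np.full(5, 0.2))
        np.testing.assert_allclose(w.compute_wqs(q, weights), w.compute_wqs(permuted, wp))

    def test_single_component_equals_estimated_path(self, small_study):
        q, z, y = _training_arrays(small_study)
        q1 = pd.DataFrame({"only": q[:, 0]})
        eq = w.fit_equal_weights(q1, z, y)
        est = w.fit_constrained(q1, z, y)
        assert eq.beta1 == pytest.approx(est.beta1, abs=1e-8)


class TestRunWQS:
    def test_positive_truth_recovers_positive_direction(self, small_study):
        fit = w.run_wqs(small_study.individuals, small_study.areas, small_study.spec,
                        w.WQSOptions(B=5, split_seed=1, bootstrap_seed=2))
        assert fit.odds_ratio > 1.0
        assert fit.weights.w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_same_seeds_identical_fit(self, small_study):
        opts = w.WQSOptions(B=3, split_seed=4, bootstrap_seed=5)
        a = w.run_wqs(small_study.individuals, small_study.areas, small_study.spec, opts)
        b = w.run_wqs(small_study.individuals, small_study.areas, small_study.spec, opts)
        assert a.to_dict() == b.to_dict()

    def test_provenance_recorded(self, small_study):
        opts = w.WQSOptions(B=2, split_seed=8, bootstrap_seed=9, fraction=0.5)
        fit = w.run_wqs(small_study.individuals, small_study.areas, small_study.spec, opts)
        assert fit.provenance["split_seed"] == 8
        assert fit.provenance["B"] == 2
        assert fit.provenance["n_total"] == len(small_study.individuals)

    def test_zscore_mode_runs(self, small_study):
        fit = w.run_wqs(small_study.individuals, small_study.areas, small_study.spec,
                        w.WQSOptions(B=2, mode="zscore", split_seed=1, bootstrap_seed=2))
        assert fit.mode == "zscore"
        assert np.isfinite(fit.aic)
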