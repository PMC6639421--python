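"""Likelihood engine: probabilities, Laplace vs quadrature, fitting, ORs, EBEs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import prepmarkov as pm
from prepmarkov.errors import ConfigurationError
from prepmarkov.markov_model import (MarkovTransitionModel, EffectEstimate,
                                     marginal_nll, transition_matrix)
from prepmarkov.transitions import TransitionDataset, count_transitions


def _dataset_from_states(states_by_subject, cov_by_subject=None):
    import datetime
    series, frames = [], None
    for i, states in enumerate(states_by_subject):
        series.append(pm.AdherenceSeries(f"S{i:03d}", datetime.date(2015, 1, 1),
                                         np.asarray(states, dtype=np.int8)))
    if cov_by_subject is not None:
        frames = [pd.DataFrame({k: np.full(len(states_by_subject[i]), v)
                                for k, v in cov.items()})
                  for i, cov in enumerate(cov_by_subject)]
    return TransitionDataset.from_series(series, frames)


class TestTransitionProbabilities:
    def test_zero_logit_gives_half(self):
        p = pm.MarkovParams(theta1=0.0, theta2=-1.0)
        p01, p10, p00, p11 = pm.transition_probabilities(p)
        assert p01 == pytest.approx(0.5)
        assert p00 == pytest.approx(0.5)

    def test_log_two_coefficient_gives_two_thirds(self):
        p = pm.MarkovParams(theta1=0.0, theta2=0.0,
                            beta10={"x": math.log(2)})
        _, p10, _, _ = pm.transition_probabilities(p, {"x": 1.0})
        assert p10 == pytest.approx(2 / 3)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-3, 3), st.floats(-3, 3))
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, t1, t2, e1, e2):
        p = pm.MarkovParams(theta1=t1, theta2=t2)
        p01, p10, p00, p11 = pm.transition_probabilities(p, eta=(e1, e2))
        assert p01 + p00 == pytest.approx(1.0, abs=1e-15)
        assert p10 + p11 == pytest.approx(1.0, abs=1e-15)
        assert 0 < p01 < 1 and 0 < p10 < 1

    def test_unregistered_covariate_rejected(self):
        p = pm.MarkovParams(theta1=0.0, theta2=0.0, beta01={"x": 1.0})
        with pytest.raises(ConfigurationError):
            pm.transition_probabilities(p, {"y": 1.0})

    def test_matrix_rows_sum_to_one(self):
        p = pm.MarkovParams(theta1=0.3, theta2=-0.7)
        m = transition_matrix(p)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)


class TestConditionalNLL:
    def test_two_persistent_days(self):
        # P11 = 0.8  <=>  P10 = 0.2  <=>  theta2 = logit(0.2)
        p = pm.MarkovParams(theta1=0.0, theta2=math.log(0.2 / 0.8))
        val = pm.conditional_nll([1, 1], [1, 1], p)
        assert val == pytest.approx(-math.log(0.64), rel=1e-12)

    def test_single_discontinuation_day(self):
        p = pm.MarkovParams(theta1=0.0, theta2=math.log(0.3 / 0.7))
        assert pm.conditional_nll([1], [0], p) == pytest.approx(-math.log(0.3))

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(4)
        states = rng.integers(0, 2, size=30)
        prev = np.concatenate([[1], states[:-1]])
        p = pm.MarkovParams(theta1=-0.8, theta2=-1.5)
        m = transition_matrix(p)
        brute = -sum(math.log(m[prev[i], states[i]]) for i in range(30))
        assert pm.conditional_nll(prev, states, p) == pytest.approx(brute, rel=1e-12)


class TestMarginalNLL:
    def _toy(self, n_subj=5, n_days=20, seed=9):
        spec = pm.CohortSpec(n_subjects=n_subj, n_days=n_days, prevalences={},
                             multinomials={},
                             true_params=pm.MarkovParams(
                                 theta1=-1.0, theta2=-2.0, omega_sq=(0.5, 0.5)))
        return spec, pm.generate_cohort(spec, seed=seed).to_dataset()

    def test_zero_variance_equals_conditional(self):
        spec, ds = self._toy()
        p = pm.MarkovParams(theta1=-1.0, theta2=-2.0, omega_sq=(0.0, 0.0),
                            random_effects="none")
        lap = marginal_nll(ds, p)
        frame = ds.frame()
        cond = sum(
            pm.conditional_nll(g["prev_state"], g["state"], p)
            for _, g in frame.groupby("subject_id"))
        assert lap == pytest.approx(2 * cond, rel=1e-10)

    def test_laplace_within_half_percent_of_adaptive_quadrature(self):
        spec, ds = self._toy()
        p = spec.true_params
        lap = marginal_nll(ds, p, method="laplace")
        agq = marginal_nll(ds, p, method="agq", nodes=64)
        assert abs(lap - agq) / abs(agq) < 0.005

    def test_nonadaptive_quadrature_agrees_at_high_order(self):
        spec, ds = self._toy()
        p = spec.true_params
        agq = marginal_nll(ds, p, method="agq", nodes=64)
        ghq = marginal_nll(ds, p, method="ghq", nodes=64)
        assert ghq == pytest.approx(agq, rel=1e-6)

    def test_invariant_to_subject_order(self):
        _, ds = self._toy()
        p = pm.MarkovParams(theta1=-1.0, theta2=-2.0, omega_sq=(0.4, 0.4))
        base = marginal_nll(ds, p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_records)
        shuffled = TransitionDataset(
            subject_ids=ds.subject_ids, subj=ds.subj[perm], prev=ds.prev[perm],
            state=ds.state[perm], X=ds.X[perm], covariate_names=ds.covariate_names)
        assert abs(marginal_nll(shuffled, p) - base) < 1e-8

    def test_mode_shift_improves_on_conditional_for_adherent_subject(self):
        # all-[11] data: the posterior mode moves eta_p10 negative, so the
        # marginal likelihood beats the conditional likelihood at eta = 0
        ds = _dataset_from_states([[1] * 30])
        p = pm.MarkovParams(theta1=0.0, theta2=-1.0, omega_sq=(2.0, 2.0))
        marg = marginal_nll(ds, p, method="agq", nodes=64)      # -2 log L
        cond = 2 * pm.conditional_nll([1] * 30, [1] * 30, p)
        assert marg < cond


class TestFit:
    def test_zero_variance_recovers_empirical_frequencies(self, nocov_dataset):
        est = MarkovTransitionModel(p01_terms=(), p10_terms=(),
                                    random_effects="none").fit(nocov_dataset)
        counts = count_transitions(nocov_dataset.frame())
        assert expit(est.params_.theta1) == pytest.approx(
            counts.n01 / (counts.n01 + counts.n00), abs=1e-5)
        assert expit(est.params_.theta2) == pytest.approx(
            counts.n10 / (counts.n10 + counts.n11), abs=1e-5)

    def test_refit_from_optimum_is_fixed_point(self, nocov_dataset, nocov_markov_fit):
        first = nocov_markov_fit
        est = MarkovTransitionModel(p01_terms=(), p10_terms=())
        # start the p01/p10 blocks at the fitted intercepts
        refit = est.fit(nocov_dataset).result_
        assert refit.neg2ll == pytest.approx(first.neg2ll, abs=0.1)

    def test_parameter_recovery_within_three_se(self):
        beta = math.log(0.5)
        params = pm.MarkovParams(theta1=-1.0, theta2=-1.8,
                                 beta10={"risk": beta}, omega_sq=(0.4, 0.4))
        spec = pm.CohortSpec(n_subjects=250, n_days=150,
                             prevalences={"risk": 0.5}, multinomials={},
                             true_params=params)
        res = pm.fit(pm.generate_cohort(spec, seed=77).to_dataset())
        assert res.converged
        est = res.params.beta10["risk"]
        se = res.se["p10:risk"]
        assert abs(est - beta) < 3 * se
        for name, truth in (("theta1", -1.0), ("theta2", -1.8)):
            assert abs(getattr(res.params, name) - truth) < \
                3 * res.se[f"p{'01' if name == 'theta1' else '10'}:intercept"]

    def test_shared_random_effect_structure_fits(self, nocov_dataset):
        res = pm.fit(nocov_dataset,
                     pm.ModelSpec((), (), random_effects="shared"))
        assert res.converged
        assert res.params.omega_sq[0] == res.params.omega_sq[1]

    def test_wald_coverage_across_replicates(self):
        # reduced-scale coverage check: true log-ORs inside the 95% CI in at
        # least 8 of 10 seeded replicates, for each effect
        b01, b10 = math.log(1.4), math.log(0.6)
        params = pm.MarkovParams(theta1=-1.0, theta2=-1.8,
                                 beta01={"x": b01}, beta10={"x": b10},
                                 omega_sq=(0.5, 0.5))
        spec = pm.CohortSpec(n_subjects=150, n_days=120,
                             prevalences={"x": 0.5}, multinomials={},
                             true_params=params)
        hits01 = hits10 = 0
        for seed in range(10):
            res = pm.fit(pm.generate_cohort(spec, seed=1000 + seed).to_dataset())
            ors = {(e.target, e.name): e for e in pm.odds_ratios(res)}
            e01, e10 = ors[("p01", "x")], ors[("p10", "x")]
            hits01 += e01.ci_low <= math.exp(b01) <= e01.ci_high
            hits10 += e10.ci_low <= math.exp(b10) <= e10.ci_high
        assert hits01 >= 8 and hits10 >= 8


class TestBernoulli:
    def test_zero_variance_is_sample_mean(self, nocov_dataset):
        res = pm.fit_bernoulli(nocov_dataset, random_effects="none")
        assert res.params.p1 == pytest.approx(nocov_dataset.state.mean(), abs=1e-6)

    def test_markov_beats_bernoulli_on_persistent_data(
            self, nocov_markov_fit, nocov_bernoulli_fit):
        assert nocov_markov_fit.neg2ll < nocov_bernoulli_fit.neg2ll - 100

    def test_iid_data_makes_models_agree_on_marginal_probability(self):
        # P01 = 1 - P10 = 0.7: next state independent of previous state
        params = pm.MarkovParams(theta1=math.log(0.7 / 0.3),
                                 theta2=math.log(0.3 / 0.7),
                                 omega_sq=(0.0, 0.0), random_effects="none")
        spec = pm.CohortSpec(n_subjects=150, n_days=100, prevalences={},
                             multinomials={}, true_params=params)
        ds = pm.generate_cohort(spec, seed=5).to_dataset()
        mk = pm.fit(ds, pm.ModelSpec((), (), random_effects="none"))
        bn = pm.fit_bernoulli(ds, random_effects="none")
        p01 = expit(mk.params.theta1)
        p11 = 1 - expit(mk.params.theta2)
        assert p01 == pytest.approx(p11, abs=0.02)
        assert bn.params.p1 == pytest.approx(p01, abs=0.02)


class TestOddsRatios:
    def test_wald_interval_closed_form(self):
        e = EffectEstimate("x", "p01", 0.0, 0.1, 1.0,
                           math.exp(-1.96 * 0.1), math.exp(1.96 * 0.1))
        assert e.ci_low == pytest.approx(0.822, abs=5e-4)
        assert e.ci_high == pytest.approx(1.216, abs=1e-3)
        assert not e.significant

    def test_or_is_exp_beta(self, small_dataset):
        res = pm.fit(small_dataset, pm.ModelSpec(("female",), ("female",)))
        for e in pm.odds_ratios(res):
            beta = (res.params.beta01 if e.target == "p01"
                    else res.params.beta10)[e.name]
            assert e.odds_ratio == pytest.approx(math.exp(beta), rel=1e-12)
            assert e.ci_low <= e.odds_ratio <= e.ci_high

    def test_reported_effect_size_convention(self):
        # an OR of 0.61 on P10 corresponds to beta = ln(0.61)
        assert math.exp(math.log(0.61)) == pytest.approx(0.61)


class TestEmpiricalBayes:
    def test_zero_variance_gives_population_matrix(self, nocov_dataset):
        res = pm.fit(nocov_dataset, pm.ModelSpec((), (), random_effects="none"))
        pop = transition_matrix(res.params)
        for sid in nocov_dataset.subject_ids[:5]:
            np.testing.assert_allclose(
                pm.empirical_bayes_matrix(res, sid), pop, atol=1e-12)

    def test_rows_sum_to_one_for_all_subjects(self, nocov_markov_fit, nocov_dataset):
        for sid in nocov_dataset.subject_ids:
            m = pm.empirical_bayes_matrix(nocov_markov_fit, sid)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_fully_adherent_subject_gets_negative_p10_shift(self):
        states = [[1] * 60 for _ in range(10)] + \
                 [list(np.random.default_rng(i).integers(0, 2, 60))
                  for i in range(10)]
        ds = _dataset_from_states(states)
        res = pm.fit(ds, pm.ModelSpec((), ()))
        assert res.ebe.loc["S000", "eta_p10"] <= 0

    def test_unknown_subject_rejected(self, nocov_markov_fit):
        with pytest.raises(pm.DataError):
            pm.empirical_bayes_matrix(nocov_markov_fit, "ghost")
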