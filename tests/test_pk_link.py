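"""PK superposition: closed forms vs ODE oracle, thresholds, covariate panels."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import prepmarkov as pm
from prepmarkov.errors import ConfigurationError, DataError
from prepmarkov.pk_link import (ILLUSTRATIVE_TFV_PARAMS, DoseHistory, PKParams,
                                chain_to_doses, covariate_profile_panel,
                                simulate_profile, threshold_metrics)

ONE_CPT = PKParams(ka=1.2, cl_f=40.0, v_f=500.0, dose_mg=300.0)
TWO_CPT = ILLUSTRATIVE_TFV_PARAMS


def _ode_profile(doses, p, grid):
    """Numerical reference: integrate the compartment ODEs (amounts) with
    bolus inputs into the gut compartment at the dose times."""

    def rhs_amounts(t, y):
        if p.n_compartments == 1:
            gut, a = y
            return [-p.ka * gut, p.ka * gut - (p.cl_f / p.v_f) * a]
        gut, a, ap = y
        return [-p.ka * gut,
                p.ka * gut - (p.cl_f / p.v_f) * a
                - (p.q / p.v_f) * a + (p.q / p.vp) * ap,
                (p.q / p.v_f) * a - (p.q / p.vp) * ap]

    y = np.zeros(2 if p.n_compartments == 1 else 3)
    out = np.zeros_like(grid)
    eval_mask_done = np.zeros(len(grid), dtype=bool)
    events = sorted(set(doses.times))
    segments = [0.0] + [t for t in events if t > 0] + [grid[-1]]
    if doses.times.size and doses.times[0] == 0.0:
        y[0] += doses.amounts[0]
    for seg_start, seg_end in zip(segments[:-1], segments[1:]):
        mask = (grid > seg_start) & (grid <= seg_end) & ~eval_mask_done
        t_eval = grid[mask]
        sol = solve_ivp(rhs_amounts, (seg_start, seg_end), y,
                        t_eval=t_eval if len(t_eval) else None,
                        rtol=1e-11, atol=1e-13, method="LSODA")
        if len(t_eval):
            out[mask] = sol.y[1, :] / p.v_f * 1000.0
            eval_mask_done |= mask
        y = sol.y[:, -1].copy()
        for t0, amt in zip(doses.times, doses.amounts):
            if t0 == seg_end:
                y[0] += amt
    out[grid <= 0] = 0.0
    return out


class TestChainToDoses:
    def test_daily_chain_gives_daily_doses(self):
        d = chain_to_doses(np.ones(30, dtype=int), dose_time_of_day=8.0)
        assert len(d) == 30
        np.testing.assert_allclose(np.diff(d.times), 24.0)
        assert d.times[0] == 8.0

    def test_all_missed_chain_gives_empty_history(self):
        assert len(chain_to_doses([0, 0, 0])) == 0

    def test_skipped_day_skips_dose(self):
        d = chain_to_doses([1, 0, 1], dose_time_of_day=0.0)
        np.testing.assert_allclose(d.times, [0.0, 48.0])

    def test_empty_chain_rejected(self):
        with pytest.raises(DataError):
            chain_to_doses([])


class TestSimulateProfile:
    grid = np.arange(0.0, 96.0, 0.25)

    def test_no_doses_gives_zero_profile(self):
        prof = simulate_profile(DoseHistory([], []), ONE_CPT, self.grid)
        assert (prof.concentrations == 0).all()

    def test_superposition_of_two_doses(self):
        d1 = DoseHistory([8.0], [300.0])
        d2 = DoseHistory([32.0], [300.0])
        both = DoseHistory([8.0, 32.0], [300.0, 300.0])
        c = simulate_profile(both, ONE_CPT, self.grid).concentrations
        c1 = simulate_profile(d1, ONE_CPT, self.grid).concentrations
        c2 = simulate_profile(d2, ONE_CPT, self.grid).concentrations
        np.testing.assert_allclose(c, c1 + c2, rtol=1e-12)

    def test_dose_linearity(self):
        d = DoseHistory([0.0, 24.0], [300.0, 300.0])
        d2 = DoseHistory([0.0, 24.0], [600.0, 600.0])
        c = simulate_profile(d, ONE_CPT, self.grid).concentrations
        cc = simulate_profile(d2, ONE_CPT, self.grid).concentrations
        np.testing.assert_allclose(cc, 2 * c, rtol=1e-12)

    def test_removing_a_dose_never_raises_concentration(self):
        full = DoseHistory([0.0, 24.0, 48.0], [300.0] * 3)
        less = DoseHistory([0.0, 48.0], [300.0] * 2)
        cf = simulate_profile(full, TWO_CPT, self.grid).concentrations
        cl = simulate_profile(less, TWO_CPT, self.grid).concentrations
        assert (cl <= cf + 1e-12).all()

    @pytest.mark.parametrize("params", [ONE_CPT, TWO_CPT],
                             ids=["one_compartment", "two_compartment"])
    def test_closed_form_matches_ode_oracle(self, params):
        doses = DoseHistory([6.0], [300.0])
        grid = np.arange(0.0, 72.0, 1.0)
        analytic = simulate_profile(doses, params, grid).concentrations
        numeric = _ode_profile(doses, params, grid)
        sel = grid >= 7.0          # past absorption onset, values O(100) ng/mL
        rel = np.abs(analytic[sel] - numeric[sel]) / numeric[sel]
        assert rel.max() < 1e-6

    def test_randomized_two_compartment_draws_match_ode(self):
        rng = np.random.default_rng(123)
        for _ in range(3):
            p = PKParams(ka=float(rng.uniform(0.3, 2.0)),
                         cl_f=float(rng.uniform(10, 80)),
                         v_f=float(rng.uniform(100, 700)),
                         q=float(rng.uniform(50, 300)),
                         vp=float(rng.uniform(200, 900)))
            doses = DoseHistory([3.0], [300.0])
            grid = np.arange(0.0, 48.0, 1.0)
            analytic = simulate_profile(doses, p, grid).concentrations
            numeric = _ode_profile(doses, p, grid)
            sel = grid >= 4.0
            assert (np.abs(analytic[sel] - numeric[sel]) / numeric[sel]).max() < 1e-6

    def test_absorption_elimination_tie_uses_limit_branch(self):
        ka = 0.8
        tied = PKParams(ka=ka, cl_f=ka * 500.0, v_f=500.0)     # ke == ka
        near = PKParams(ka=ka, cl_f=(ka + 1e-7) * 500.0, v_f=500.0)
        doses = DoseHistory([0.0], [300.0])
        grid = np.arange(0.5, 48.0, 0.5)
        c_tied = simulate_profile(doses, tied, grid).concentrations
        c_near = simulate_profile(doses, near, grid).concentrations
        np.testing.assert_allclose(c_tied, c_near, rtol=1e-4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            PKParams(ka=-1.0, cl_f=40.0, v_f=500.0)
        with pytest.raises(ConfigurationError):
            PKParams(ka=1.0, cl_f=40.0, v_f=500.0, q=100.0)   # vp missing


class TestThresholdMetrics:
    def test_profile_entirely_above_threshold(self):
        prof = pm.ConcentrationProfile([0.0, 1.0, 2.0], [50.0, 60.0, 55.0])
        m = threshold_metrics(prof, 40.0)
        assert m.fraction_below == 0.0
        assert m.first_below_h is None

    def test_constant_profile_exactly_at_threshold_not_below(self):
        prof = pm.ConcentrationProfile([0.0, 1.0, 2.0], [40.0, 40.0, 40.0])
        assert threshold_metrics(prof, 40.0).fraction_below == 0.0

    def test_linear_crossing_interpolated(self):
        # falls linearly 80 -> 0 over 2 h; crosses 40 at t = 1
        prof = pm.ConcentrationProfile([0.0, 2.0], [80.0, 0.0])
        m = threshold_metrics(prof, 40.0)
        assert m.fraction_below == pytest.approx(0.5)
        assert m.first_below_h == pytest.approx(1.0)
        assert m.longest_below_h == pytest.approx(1.0)

    def test_gap_in_dosing_increases_time_below(self):
        grid = np.arange(0.0, 30 * 24.0, 0.5)
        full = chain_to_doses(np.ones(30, dtype=int))
        gap_chain = np.ones(30, dtype=int)
        gap_chain[10:15] = 0
        gappy = chain_to_doses(gap_chain)
        mf = threshold_metrics(simulate_profile(full, TWO_CPT, grid))
        mg = threshold_metrics(simulate_profile(gappy, TWO_CPT, grid))
        assert mg.fraction_below >= mf.fraction_below
        assert mg.longest_below_h >= mf.longest_below_h


class TestCovariateProfilePanel:
    def _params(self, b01=0.0, b10=0.0):
        return pm.MarkovParams(theta1=-1.0, theta2=-2.0,
                               beta01={"x": b01}, beta10={"x": b10})

    def test_null_effect_gives_identical_matrices(self):
        panel = covariate_profile_panel(self._params(0.0, 0.0), "x",
                                        pk=TWO_CPT, seed=1)
        np.testing.assert_allclose(panel[0]["matrix"], panel[1]["matrix"])

    def test_deterministic_under_seed(self):
        a = covariate_profile_panel(self._params(0.5, -0.5), "x",
                                    pk=TWO_CPT, seed=4)
        b = covariate_profile_panel(self._params(0.5, -0.5), "x",
                                    pk=TWO_CPT, seed=4)
        np.testing.assert_array_equal(a[1]["chain"], b[1]["chain"])
        np.testing.assert_allclose(a[1]["profile"].concentrations,
                                   b[1]["profile"].concentrations)

    def test_protective_category_misses_fewer_days(self):
        # category 1: higher P01, lower P10 -> stochastically fewer misses
        params = self._params(b01=1.0, b10=-1.0)
        rng = np.random.default_rng(9)
        miss0 = miss1 = 0
        from prepmarkov.markov_model import transition_matrix
        from prepmarkov.ntt_diagnostics import simulate_chain
        m0 = transition_matrix(params, {"x": 0.0})
        m1 = transition_matrix(params, {"x": 1.0})
        for _ in range(200):
            miss0 += (simulate_chain(m0, 30, rng=rng) == 0).sum()
            miss1 += (simulate_chain(m1, 30, rng=rng) == 0).sum()
        assert miss1 < miss0

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ConfigurationError):
            covariate_profile_panel(self._params(), "ghost", pk=TWO_CPT, seed=0)
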