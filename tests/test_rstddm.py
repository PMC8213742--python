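"""Core model tests: drift schedule, simulator, FPT solver, likelihood."""

import numpy as np
import pandas as pd
import pytest

from cuedfood import analytic, rstddm
from cuedfood.params import RstDDMParams


def _constant_mu(p, td, hd):
    return p.drift_bias + p.w_taste * td + p.w_health * hd


class TestDriftSchedule:
    def test_zero_rst_reduces_to_constant_drift(self):
        p = RstDDMParams(rst=0.0, w_taste=0.5, w_health=0.3, drift_bias=0.1)
        t = np.linspace(0, 2, 9)
        mu = rstddm.drift_at(p, 1.0, -2.0, t)
        assert np.allclose(mu, _constant_mu(p, 1.0, -2.0))

    def test_delayed_health_onset(self):
        p = RstDDMParams(rst=0.18, w_taste=0.9, w_health=0.8)
        before = rstddm.drift_at(p, 1.0, 1.0, 0.1)
        after = rstddm.drift_at(p, 1.0, 1.0, 0.2)
        assert before == pytest.approx(0.9)
        assert after == pytest.approx(0.9 + 0.8)

    def test_delayed_taste_onset_for_negative_rst(self):
        p = RstDDMParams(rst=-0.2, w_taste=0.9, w_health=0.8)
        assert rstddm.drift_at(p, 1.0, 1.0, 0.1) == pytest.approx(0.8)
        assert rstddm.drift_at(p, 1.0, 1.0, 0.25) == pytest.approx(1.7)

    def test_zero_weights_give_pure_bias(self):
        p = RstDDMParams(rst=0.3, drift_bias=-0.4)
        assert rstddm.drift_at(p, 3.0, -3.0, 1.0) == pytest.approx(-0.4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rstddm.drift_at(RstDDMParams(), 0.0, 0.0, -0.1)


class TestSimulator:
    def test_symmetric_parameters_give_even_split(self):
        p = RstDDMParams(noise=1.0, sp_bias=0.5, ndt=0.3)
        df = rstddm.simulate_trials(p, np.zeros(40000), np.zeros(40000),
                                    seed=1, deadline=30.0)
        phat = (df["chose_left"] == 1).mean()
        se = np.sqrt(0.25 / len(df))
        assert abs(phat - 0.5) < 3 * se

    def test_matches_constant_drift_absorption_probability(self):
        p = RstDDMParams(noise=1.1, sp_bias=0.55, ndt=0.4,
                         w_taste=0.6, w_health=-0.2, drift_bias=0.05)
        mu = _constant_mu(p, 1.5, 1.0)
        target = analytic.prob_upper(mu, p.x0, p.noise)
        df = rstddm.simulate_trials(p, np.full(50000, 1.5), np.full(50000, 1.0),
                                    seed=2, deadline=30.0)
        phat = (df["chose_left"] == 1).mean()
        se = np.sqrt(target * (1 - target) / len(df))
        assert abs(phat - target) < 3 * se

    def test_step_size_refinement_is_stable(self):
        """Halving dt moves P(left) and mean RT by less than the Monte-Carlo
        scale — the bridge-corrected scheme has no visible O(sqrt(dt)) bias."""
        p = RstDDMParams(noise=1.0, ndt=0.5, w_taste=0.8, rst=0.1, w_health=0.4)
        stats = {}
        for dt in (0.004, 0.002):
            df = rstddm.simulate_trials(p, np.full(30000, 1.0),
                                        np.full(30000, 0.5), dt=dt, seed=3)
            kept = df[~df["censored"]]
            stats[dt] = ((kept["chose_left"] == 1).mean(), kept["rt"].mean())
        assert abs(stats[0.004][0] - stats[0.002][0]) < 0.012
        assert abs(stats[0.004][1] - stats[0.002][1]) < 0.015

    def test_reproducible_and_censoring_flagged(self):
        p = RstDDMParams(noise=1.0, ndt=0.6, w_taste=0.3)
        a = rstddm.simulate_trials(p, [0.2] * 500, [0.1] * 500, seed=9)
        b = rstddm.simulate_trials(p, [0.2] * 500, [0.1] * 500, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert a.loc[a["censored"], "rt"].isna().all()
        kept = a.loc[~a["censored"], "rt"]
        assert ((kept > p.ndt) & (kept <= 3.0)).all()

    def test_invalid_inputs_rejected(self):
        p = RstDDMParams()
        with pytest.raises(ValueError):
            rstddm.simulate_trials(p, [np.nan], [0.0])
        with pytest.raises(ValueError):
            rstddm.simulate_trials(p, [0.0], [0.0], dt=0.0)


class TestFPTDensity:
    CASES = [
        RstDDMParams(noise=1.0, sp_bias=0.5, ndt=0.5, w_taste=0.6),
        RstDDMParams(noise=1.2, sp_bias=0.6, ndt=0.5, w_taste=0.9,
                     w_health=-0.13, rst=0.18),
        RstDDMParams(noise=0.98, sp_bias=0.49, ndt=0.59, w_taste=0.32,
                     w_health=0.9, rst=-0.03),
    ]

    @pytest.mark.parametrize("p", CASES)
    def test_mass_conservation(self, p):
        grid = np.arange(0.005, 3.0, 0.005)
        d = rstddm.fpt_density(p, 1.0, 1.0, grid)
        total = d.absorbed_mass() + d.survival[-1]
        assert abs(total - 1.0) < 1e-4

    def test_matches_series_solution_without_rst(self):
        p = RstDDMParams(noise=1.05, sp_bias=0.55, w_taste=0.5,
                         w_health=0.2, drift_bias=0.1)
        grid = np.arange(0.01, 2.5, 0.01)
        d = rstddm.fpt_density(p, 1.2, -0.8, grid)
        mu = _constant_mu(p, 1.2, -0.8)
        up, lo = analytic.fpt_density_constant_drift(grid, mu, p.x0, p.noise)
        assert np.max(np.abs(d.upper - up)) < 5e-3
        assert np.max(np.abs(d.lower - lo)) < 5e-3

    def test_grid_validation_and_stability_errors(self):
        p = RstDDMParams(w_taste=1.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            rstddm.fpt_density(p, 1.0, 0.0, [0.5, 0.4])
        with pytest.raises(ValueError, match="Peclet"):
            rstddm.fpt_density(p, 9.0, 0.0, [0.5, 1.0], nx=9)

    def test_upper_probability_increases_with_health_evidence(self):
        """Monotonicity: more health evidence weakly raises P(upper)."""
        grid = np.arange(0.01, 6.0, 0.01)
        masses = []
        for hd in (0.0, 1.0, 2.0, 4.0):
            p = RstDDMParams(noise=1.0, w_taste=0.4, w_health=0.6, rst=0.1)
            d = rstddm.fpt_density(p, 0.5, hd, grid)
            masses.append(np.trapezoid(d.upper, grid))
        assert np.all(np.diff(masses) > 0)


class TestLoglik:
    def test_empty_after_censoring_returns_zero_with_warning(self):
        p = RstDDMParams()
        trials = pd.DataFrame({"td_lr": [1.0], "hd_lr": [0.0],
                               "chose_left": [-1], "rt": [np.nan],
                               "censored": [True]})
        with pytest.warns(UserWarning, match="no non-censored"):
            assert rstddm.loglik(p, trials) == 0.0

    def test_single_trial_equals_log_density(self):
        p = RstDDMParams(noise=1.0, ndt=0.5, w_taste=0.7, w_health=0.2, rst=0.12)
        rt = 1.1
        trials = pd.DataFrame({"td_lr": [1.5], "hd_lr": [-0.5],
                               "chose_left": [1], "rt": [rt],
                               "censored": [False]})
        ll = rstddm.loglik(p, trials, nx=161, dt_max=0.004)
        d = rstddm.fpt_density(p, 1.5, -0.5, np.array([rt - p.ndt]),
                               nx=161, dt_max=0.004)
        assert ll == pytest.approx(np.log(d.upper[0]), rel=1e-9)

    def test_rt_below_ndt_is_reported_with_trial_index(self):
        p = RstDDMParams(ndt=0.9)
        trials = pd.DataFrame({"td_lr": [1.0, 1.0], "hd_lr": [0.0, 0.0],
                               "chose_left": [1, 0], "rt": [1.2, 0.6],
                               "censored": [False, False]})
        with pytest.raises(ValueError, match="trial 1"):
            rstddm.loglik(p, trials)

    def test_generative_parameters_beat_perturbed_taste_weight(self):
        """Likelihood dominance on a large simulated set."""
        p = RstDDMParams(noise=1.0, sp_bias=0.5, ndt=0.5, rst=0.1,
                         w_taste=0.8, w_health=0.4, drift_bias=0.0)
        rng = np.random.default_rng(11)
        td = rng.uniform(-4, 4, 5000)
        hd = rng.uniform(-3, 3, 5000)
        trials = rstddm.simulate_trials(p, td, hd, seed=12)
        ll_true = rstddm.loglik(p, trials)
        for factor in (0.5, 1.5):
            ll_bad = rstddm.loglik(p.with_(w_taste=p.w_taste * factor), trials)
            assert ll_true > ll_bad

    def test_truncation_policy_renormalises(self):
        p = RstDDMParams(noise=1.0, ndt=0.5, w_taste=0.4)
        trials = pd.DataFrame({"td_lr": [1.0], "hd_lr": [0.0],
                               "chose_left": [1], "rt": [1.0],
                               "censored": [False]})
        ll_ex = rstddm.loglik(p, trials, deadline_policy="exclude")
        ll_tr = rstddm.loglik(p, trials, deadline_policy="truncate")
        # dividing by P(respond before deadline) < 1 raises the density
        assert ll_tr > ll_ex
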