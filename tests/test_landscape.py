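"""Cost landscapes, softmax selection, and developmental dynamics."""

import warnings

import numpy as np
import pytest

from vocaldev import landscape as ls
from vocaldev.call_catalog import GainLandscape


def toy_landscape(n=111, cry_hi=0.3, phee_lo=0.6, g_cry=0.5, g_phee=0.9):
    """Piecewise-constant gain landscape with known region geometry."""
    theta = np.linspace(0.0, 1.1, n)
    g = np.full(n, np.nan)
    labels = np.array(["none"] * n, dtype=object)
    cry = (theta > 0.1) & (theta <= cry_hi)
    sub = (theta > cry_hi) & (theta < phee_lo)
    phee = theta >= phee_lo
    g[cry], labels[cry] = g_cry, "cry"
    g[sub], labels[sub] = 0.4, "subharmonic_phee"
    g[phee], labels[phee] = g_phee, "phee"
    return GainLandscape(theta, g, labels, 50.0)


class TestCosts:
    def test_unit_gain_gives_zero_cost(self):
        gl = toy_landscape(g_cry=1.0, g_phee=1.0)
        C = ls.cost_basic(gl)
        voiced = gl.labels != "none"
        assert np.all(C.C[voiced & (gl.g == 1.0)] == 0.0)

    def test_log_identity(self):
        gl = toy_landscape()
        gl.g[gl.labels != "none"] = np.e
        C = ls.cost_basic(gl)
        np.testing.assert_allclose(C.C[gl.labels != "none"], -1.0)

    def test_unvoiced_cells_have_infinite_cost(self):
        C = ls.cost_basic(toy_landscape())
        assert np.all(np.isinf(C.C[C.labels == "none"]))

    def test_cost_trough_at_gain_peak(self, gl_small):
        C = ls.cost_basic(gl_small)
        assert np.nanargmax(gl_small.g) == np.argmin(
            np.where(np.isfinite(C.C), C.C, np.inf))

    def test_muscular_term_reduces_to_basic_at_zero(self, gl_small):
        np.testing.assert_array_equal(ls.cost_muscular(gl_small, 0.0).C,
                                      ls.cost_basic(gl_small).C)

    def test_muscular_term_is_linear_tilt(self):
        gl = toy_landscape()
        lam = 0.8
        C0, C1 = ls.cost_basic(gl), ls.cost_muscular(gl, lam)
        i, j = 40, 100
        d0 = C0.C[j] - C0.C[i]
        d1 = C1.C[j] - C1.C[i]
        assert d1 - d0 == pytest.approx(lam * (gl.theta[j] - gl.theta[i]))

    def test_large_lambda_moves_argmin_into_cry_region(self, gl_small):
        C_lo = ls.cost_muscular(gl_small, 0.0)
        C_hi = ls.cost_muscular(gl_small, 8.0)
        lab_lo = gl_small.labels[np.argmin(np.nan_to_num(C_lo.C, posinf=1e9))]
        lab_hi = gl_small.labels[np.argmin(np.nan_to_num(C_hi.C, posinf=1e9))]
        assert lab_lo == "phee"
        assert lab_hi == "cry"


class TestLambdaDynamics:
    def test_initial_value(self):
        p = ls.DevelopmentParams(3.0, 0.2, 0.1, 0.5)
        assert ls.lambda_at(0.0, p) == 3.0

    def test_hand_computed_decay(self):
        p = ls.DevelopmentParams(3.0, 0.2, 0.1, 0.5)
        assert ls.lambda_at(5.0, p) == pytest.approx(2.0)

    def test_recursion_equals_closed_form(self):
        p = ls.DevelopmentParams(3.0, 0.2126, 0.0654, 0.122)
        lam = p.lambda0
        for t in range(1, 26):
            lam = lam - p.kappa * p.F - p.delta
            assert abs(lam - ls.lambda_at(t, p)) < 1e-12

    def test_negative_lambda_clipped_with_warning(self):
        p = ls.DevelopmentParams(1.0, 0.5, 0.5, 1.0)
        with pytest.warns(RuntimeWarning):
            assert ls.lambda_at(10.0, p) == 0.0

    def test_full_cost_reduces_to_muscular_without_development(self, gl_small):
        p = ls.DevelopmentParams(3.0, 0.0, 0.0, 0.5)
        np.testing.assert_array_equal(ls.cost_full(gl_small, p, 17.0).C,
                                      ls.cost_muscular(gl_small, 3.0).C)

    def test_without_feedback_daily_change_is_delta_theta(self):
        gl = toy_landscape()
        p = ls.DevelopmentParams(3.0, 0.2126, 0.05, 0.0)
        C1, C2 = ls.cost_full(gl, p, 4.0), ls.cost_full(gl, p, 5.0)
        voiced = gl.labels != "none"
        np.testing.assert_allclose(
            C1.C[voiced] - C2.C[voiced], p.delta * gl.theta[voiced],
            atol=1e-12)

    def test_feedback_tilt_strictly_increases_with_F(self):
        # the landscape-figure parameter column: κ=0.2126, increasing F
        gl = toy_landscape()
        t = 30.0
        tilts = []
        for F in (0.1176, 0.1566, 0.1961):
            p = ls.DevelopmentParams(3.0, 0.2126, 0.0417, F)
            C = ls.cost_full(gl, p, t)
            voiced = gl.labels != "none"
            C0 = ls.cost_full(gl, p, 0.0)
            slope = np.polyfit(gl.theta[voiced],
                               C0.C[voiced] - C.C[voiced], 1)[0]
            tilts.append(slope)
        assert tilts[0] < tilts[1] < tilts[2]


class TestSoftmax:
    def test_zero_eta_is_uniform_over_support(self):
        gl = toy_landscape()
        d = ls.softmax_density(ls.cost_basic(gl), 0.0)
        finite = np.isfinite(ls.cost_basic(gl).C)
        p_vals = d.p[finite]
        assert np.allclose(p_vals, p_vals[0])
        assert d.integral() == pytest.approx(1.0, abs=1e-9)

    def test_two_cell_hand_calculation(self):
        theta = np.array([0.1, 0.2])
        C = ls.CostLandscape(theta, np.array([0.0, np.log(2.0)]),
                             np.array(["cry", "phee"], dtype=object))
        d = ls.softmax_density(C, 1.0)
        p_cry, _, p_phee = ls.call_probabilities(
            d, np.array(["cry", "phee"], dtype=object))
        assert p_cry == pytest.approx(2.0 / 3.0)
        assert p_phee == pytest.approx(1.0 / 3.0)

    def test_normalisation_for_random_costs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            theta = np.linspace(0.0, 1.1, 57)
            C = ls.CostLandscape(theta, rng.uniform(0, 5, 57),
                                 np.array(["phee"] * 57, dtype=object))
            d = ls.softmax_density(C, rng.uniform(0, 50))
            assert d.integral() == pytest.approx(1.0, abs=1e-9)

    def test_all_infinite_cost_raises(self):
        theta = np.linspace(0, 1, 5)
        C = ls.CostLandscape(theta, np.full(5, np.inf),
                             np.array(["none"] * 5, dtype=object))
        with pytest.raises(ValueError):
            ls.softmax_density(C, 1.0)

    def test_probabilities_sum_to_one_with_zero_none_mass(self, gl_small):
        d = ls.softmax_density(ls.cost_muscular(gl_small, 1.0), 5.0)
        p = ls.call_probabilities(d, gl_small.labels)
        assert sum(p) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_density_probabilities_proportional_to_widths(self):
        gl = toy_landscape()
        d = ls.softmax_density(ls.cost_basic(gl), 0.0)
        p_cry, p_sub, p_phee = ls.call_probabilities(d, gl.labels)
        n_cry = (gl.labels == "cry").sum()
        n_phee = (gl.labels == "phee").sum()
        assert p_phee / p_cry == pytest.approx(n_phee / n_cry, rel=1e-9)

    def test_increasing_eta_increases_phee_probability(self, gl_small):
        C = ls.cost_basic(gl_small)
        p_phee = [ls.call_probabilities(ls.softmax_density(C, eta),
                                        gl_small.labels)[2]
                  for eta in (0.0, 2.0, 10.0, 50.0)]
        assert np.all(np.diff(p_phee) > 0)


class TestRatio:
    def test_equal_probabilities_give_zero(self):
        assert ls.phee_cry_ratio(0.2, 0.2) == 0.0

    def test_no_cries_gives_one(self):
        assert ls.phee_cry_ratio(0.4, 0.0) == 1.0

    def test_hand_value(self):
        assert ls.phee_cry_ratio(0.3, 0.1) == pytest.approx(0.5)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            ls.phee_cry_ratio(0.0, 0.0)


class TestLambdaZ:
    def test_matches_dense_grid_scan(self):
        gl = toy_landscape()
        eta = 20.0
        lz = ls.solve_lambda_z(gl, eta=eta, bracket=(0.0, 5.0))
        lams = np.linspace(0.0, 5.0, 20001)
        ratios = np.array([ls.model_phee_cry_ratio(gl, l, eta) for l in lams])
        i = int(np.argmin(np.abs(ratios)))
        assert abs(lz - lams[i]) <= 2 * (lams[1] - lams[0])
        assert abs(ls.model_phee_cry_ratio(gl, lz, eta)) < 1e-6

    def test_analytic_value_for_two_level_landscape(self):
        # with g constant per region the crossing balances the tilt against
        # the gain advantage; a dense scan pins the same value
        gl = toy_landscape(g_cry=0.5, g_phee=0.9)
        for eta in (10.0, 40.0):
            lz = ls.solve_lambda_z(gl, eta=eta, bracket=(0.0, 5.0))
            assert abs(ls.model_phee_cry_ratio(gl, lz, eta)) < 1e-6

    def test_ratio_monotone_decreasing_in_lambda(self, gl_small):
        lams = np.linspace(0.0, 4.0, 9)
        ratios = [ls.model_phee_cry_ratio(gl_small, l, 5.0) for l in lams]
        assert np.all(np.diff(ratios) < 0)

    def test_no_sign_change_raises(self):
        gl = toy_landscape()
        with pytest.raises(ValueError):
            ls.solve_lambda_z(gl, eta=5.0, bracket=(0.0, 1e-6))


class TestFitLambdaDaily:
    def test_recovers_generating_lambdas(self, gl_small):
        days = np.arange(0, 20)
        true_lam = np.linspace(2.5, 0.2, len(days))
        ratios = np.array([ls.model_phee_cry_ratio(gl_small, l, 5.0)
                           for l in true_lam])
        est = ls.fit_lambda_daily(days, ratios, gl_small, eta=5.0)
        np.testing.assert_allclose(est, true_lam, atol=1e-3)

    def test_zero_ratio_maps_to_lambda_z(self, gl_small):
        lz = ls.solve_lambda_z(gl_small, eta=5.0)
        est = ls.fit_lambda_daily([1, 2], [0.0, 0.0], gl_small, eta=5.0)
        np.testing.assert_allclose(est, lz, atol=1e-4)

    def test_saturated_ratio_clamps_to_range_edge(self, gl_small):
        with pytest.warns(RuntimeWarning):
            est = ls.fit_lambda_daily([1], [1.0], gl_small, eta=5.0)
        assert est[0] == 0.0


class TestZeroCrossingPrediction:
    def test_hand_value(self):
        p = ls.DevelopmentParams(3.0, 1.0, 0.0, 0.2)
        assert ls.predict_zero_crossing(p, 0.7927) == pytest.approx(11.0365)

    def test_decreasing_in_feedback(self):
        zs = [ls.predict_zero_crossing(
            ls.DevelopmentParams(3.0, 0.2126, 0.0654, F), 0.7927)
            for F in np.linspace(0.0, 1.0, 8)]
        assert np.all(np.diff(zs) < 0)

    def test_independent_of_feedback_without_learning(self):
        zs = {F: ls.predict_zero_crossing(
            ls.DevelopmentParams(3.0, 0.0, 0.0654, F), 0.7927)
            for F in (0.0, 0.5, 1.0)}
        assert len(set(zs.values())) == 1

    def test_infinite_when_no_development(self):
        p = ls.DevelopmentParams(3.0, 0.0, 0.0, 0.5)
        assert ls.predict_zero_crossing(p, 0.7927) == np.inf


class TestFitKappaDelta:
    def test_exact_recovery_from_noise_free_points(self):
        F = np.linspace(0.02, 0.35, 10)
        z0 = (3.0 - 0.7927) / (0.2126 * F + 0.0654)
        fit = ls.fit_kappa_delta(F, z0)
        assert fit.kappa == pytest.approx(0.2126, abs=1e-6)
        assert fit.delta == pytest.approx(0.0654, abs=1e-6)

    def test_all_zero_feedback_reports_nonidentifiability(self):
        z0 = np.full(5, (3.0 - 0.7927) / 0.0654)
        fit = ls.fit_kappa_delta(np.zeros(5), z0)
        assert not fit.kappa_identifiable
        assert np.isnan(fit.kappa)
        assert fit.delta == pytest.approx(0.0654, abs=1e-9)

    def test_constant_nonzero_feedback_raises(self):
        with pytest.raises(ValueError):
            ls.fit_kappa_delta(np.full(5, 0.2), np.full(5, 20.0))

    def test_noisy_recovery_at_study_scale(self):
        # 10 infants, ±1 day of crossing noise, median error within 25%
        rng = np.random.default_rng(42)
        errs_k, errs_d = [], []
        F = np.linspace(0.05, 0.3, 10)
        z0_true = (3.0 - 0.7927) / (0.2126 * F + 0.0654)
        for _ in range(100):
            z0 = z0_true + rng.normal(0.0, 1.0, 10)
            fit = ls.fit_kappa_delta(F, z0)
            errs_k.append(abs(fit.kappa - 0.2126) / 0.2126)
            errs_d.append(abs(fit.delta - 0.0654) / 0.0654)
        assert np.median(errs_k) < 0.25
        assert np.median(errs_d) < 0.25


class TestDiffusion:
    def test_flat_cost_gives_uniform_occupancy(self):
        from scipy.stats import chisquare

        theta = np.linspace(0.0, 1.0, 51)
        C = ls.CostLandscape(theta, np.zeros(51),
                             np.array(["phee"] * 51, dtype=object))
        rejections = 0
        for seed in range(10):
            run = ls.diffusion_simulate(C, eta=5.0, steps_per_day=3_000_000,
                                        step_dt=5e-4, seed=seed,
                                        record_every=20)
            w = run.theta_by_day[0][1000:]
            counts, _ = np.histogram(w, bins=np.linspace(0, 1, 11))
            # thin to roughly independent samples for the chi-square test
            thinned, _ = np.histogram(w[::60], bins=np.linspace(0, 1, 11))
            if chisquare(thinned).pvalue < 0.01:
                rejections += 1
        assert rejections <= 2

    def test_equilibrium_matches_softmax_density(self):
        theta = np.linspace(0.0, 1.1, 45)
        g = np.exp(0.5 * np.cos(6 * theta) - 0.3 * theta)
        labels = np.where(theta < 0.4, "cry", "phee").astype(object)
        gl = GainLandscape(theta, g, labels, 50.0)
        C = ls.cost_basic(gl)
        eta = 5.0
        run = ls.diffusion_simulate(C, eta, steps_per_day=30_000_000,
                                    step_dt=5e-4, seed=7, record_every=10)
        walk = run.theta_by_day[0]
        walk = walk[len(walk) // 20:]
        edges = np.linspace(theta[0], theta[-1], 23)
        emp, _ = np.histogram(walk, bins=edges)
        emp = emp / emp.sum()
        fine = np.linspace(theta[0], theta[-1], 20001)
        w = np.exp(-eta * np.interp(fine, theta, C.C))
        model = np.array([np.trapezoid(w[(fine >= a) & (fine < b)],
                                       fine[(fine >= a) & (fine < b)])
                          for a, b in zip(edges[:-1], edges[1:])])
        model = model / model.sum()
        tv = 0.5 * np.abs(emp - model).sum()
        assert tv <= 0.05

    def test_oversized_step_rejected(self):
        theta = np.linspace(0.0, 1.0, 21)
        C = ls.CostLandscape(theta, np.zeros(21),
                             np.array(["phee"] * 21, dtype=object))
        with pytest.raises(ValueError, match="step size"):
            ls.diffusion_simulate(C, eta=0.001, steps_per_day=10_000,
                                  step_dt=10.0, seed=0)

    def test_developmental_sequence_crosses_zero(self, small_cache, small_cfg):
        # full developmental cost sequence: early days cry-dominated,
        # late days phee-dominated
        p = ls.DevelopmentParams(3.0, 0.2126, 0.0654, 0.2)
        costs = []
        for day in range(0, 61, 6):
            gl = small_cache[small_cfg.half_T_at(day)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                costs.append(ls.cost_full(gl, p, day))
        run = ls.diffusion_simulate(costs, eta=5.0, steps_per_day=400_000,
                                    step_dt=5e-4, seed=1, record_every=10,
                                    emission_every=100)
        counts = run.daily_counts()
        ratio = ((counts.n_phee - counts.n_cry)
                 / (counts.n_phee + counts.n_cry).clip(lower=1))
        assert ratio.iloc[0] < 0 < ratio.iloc[-1]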