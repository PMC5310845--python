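"""Vocal-fold oscillator: Euler recursion, fixed points, bifurcations."""

import numpy as np
import pytest

from vocaldev import fold_dynamics as fd


def reference_euler(x, y, alpha, beta, gamma, dt, n_steps):
    """Plain-Python transcription of the forward-Euler recursion, used
    as the bit-level oracle for the compiled integrator."""
    xs, ys = [x], [y]
    for _ in range(n_steps):
        x_new = x + dt * y
        y_new = y + dt * (-alpha * gamma**2 - beta * gamma**2 * x
                          + gamma**2 * x**2 - gamma * x * y
                          - gamma**2 * x**3 - gamma * x**2 * y)
        x, y = x_new, y_new
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


class TestStepEuler:
    def test_origin_is_equilibrium_without_pressure(self):
        s = fd.step_euler(fd.FoldState(0.0, 0.0), fd.FoldParams(0.0, 0.7), 0.005)
        assert (s.x, s.y) == (0.0, 0.0)

    def test_single_step_hand_value(self):
        # from rest with α=0.1, γ=45: y' = −dt·αγ² = −0.005·0.1·2025
        s = fd.step_euler(fd.FoldState(0.0, 0.0), fd.FoldParams(0.1, 0.5, 45.0),
                          0.005)
        assert s.x == 0.0
        assert s.y == pytest.approx(-1.0125, abs=1e-12)

    def test_two_steps_match_reference_recursion(self):
        p = fd.FoldParams(0.151, 0.895, 45.0)
        s = fd.FoldState(0.01, 0.0)
        for _ in range(2):
            s = fd.step_euler(s, p, 0.005)
        xs, ys = reference_euler(0.01, 0.0, 0.151, 0.895, 45.0, 0.005, 2)
        assert s.x == xs[-1] and s.y == ys[-1]

    def test_blowup_raises(self):
        with pytest.raises(fd.BlowupError):
            fd.step_euler(fd.FoldState(50.0, 1e5), fd.FoldParams(1.0, 1.0), 5.0)


class TestSimulate:
    def test_step_euler_is_bitwise_identical_to_reference(self):
        xs, ys = reference_euler(0.01, 0.0, 0.3, 0.4, 45.0, 0.005, 100)
        s = fd.FoldState(0.01, 0.0)
        p = fd.FoldParams(0.3, 0.4, 45.0)
        for k in range(1, 101):
            s = fd.step_euler(s, p, 0.005)
            assert s.x == xs[k] and s.y == ys[k]

    def test_compiled_kernel_matches_reference_recursion(self):
        # the compiled kernel contracts multiply-adds to FMA, so agreement
        # is to rounding, not bit-level
        traj = fd.simulate(None, fd.FoldParams(0.3, 0.4), duration=0.5, dt=0.005)
        xs, ys = reference_euler(0.01, 0.0, 0.3, 0.4, 45.0, 0.005, 100)
        np.testing.assert_allclose(traj.x, xs, rtol=5e-13, atol=1e-15)
        np.testing.assert_allclose(traj.y, ys, rtol=5e-13, atol=1e-13)

    def test_phee_parameters_sustain_a_limit_cycle(self):
        traj = fd.simulate(None, fd.FoldParams(0.151, 0.895), duration=600.0)
        assert fd.sustained_oscillation(traj)
        # post-transient trajectory is periodic: autocorrelation of x has a
        # strong secondary peak
        x = traj.x[traj.times >= 100.0]
        x = x - x.mean()
        ac = np.correlate(x[: len(x) // 2], x, "valid")
        assert ac[1:].max() > 0.95 * ac[0]

    def test_negative_pressure_converges_to_sink(self):
        traj = fd.simulate(None, fd.FoldParams(-0.1, 0.5), duration=600.0)
        assert not fd.sustained_oscillation(traj)
        tail = traj.x[-1000:]
        assert np.ptp(tail) < 1e-6

    def test_zero_duration_returns_initial_state_only(self):
        traj = fd.simulate(None, fd.FoldParams(0.5, 0.5), duration=0.0)
        assert len(traj.times) == 1
        assert traj.x[0] == 0.01 and traj.y[0] == 0.0

    def test_schedule_ramps_are_honoured(self):
        sched = fd.ControlSchedule.ramp([0.0, 100.0], [0.0, 1.0], [0.5, 0.5])
        traj = fd.simulate(sched, fd.FoldParams(0.0, 0.0), duration=100.0)
        assert len(traj.x) == 20001


def rk45_oscillates(alpha, beta, gamma=45.0, duration=200.0):
    """Attractor classification by an adaptive RK45 integration —
    independent of the package's forward-Euler path, and free of Euler's
    spurious negative damping near weakly stable spirals."""
    from scipy.integrate import solve_ivp

    def rhs(_, s):
        x, y = s
        return [y, (-alpha * gamma**2 - beta * gamma**2 * x + gamma**2 * x**2
                    - gamma * x * y - gamma**2 * x**3 - gamma * x**2 * y)]

    ts = np.arange(0.0, duration, 0.02)
    sol = solve_ivp(rhs, (0.0, duration), [0.01, 0.0], t_eval=ts,
                    rtol=1e-7, atol=1e-9)
    traj = fd.Trajectory(sol.t, sol.y[0], sol.y[1], 0.02)
    return fd.sustained_oscillation(traj, transient_ms=duration / 2)


def long_sim_oscillates(alpha, beta, duration=400.0, dt=0.0002):
    """Long-simulation attractor check at a 25x-finer Euler step, at
    which the integrator's spurious negative damping band (width
    ~ dt ω²/2 in the decay rate) shrinks inside the 0.01 boundary
    buffer used by the sampling tests."""
    try:
        traj = fd.simulate(None, fd.FoldParams(alpha, beta),
                           duration=duration, dt=dt)
    except fd.BlowupError:
        return False
    return fd.sustained_oscillation(traj, transient_ms=duration / 2)


def brute_force_roots(alpha, beta, lo=-2.0, hi=2.0, n=40001):
    """Dense sign-change bisection scan of the fixed-point cubic."""
    xs = np.linspace(lo, hi, n)
    f = xs**3 - xs**2 + beta * xs + alpha
    roots = []
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) <= 0):
        a, b = xs[i], xs[i + 1]
        for _ in range(80):
            m = 0.5 * (a + b)
            fm = m**3 - m**2 + beta * m + alpha
            fa = a**3 - a**2 + beta * a + alpha
            if fa * fm <= 0:
                b = m
            else:
                a = m
        r = 0.5 * (a + b)
        if not roots or abs(r - roots[-1]) > 1e-6:
            roots.append(r)
    return roots


class TestFixedPoints:
    def test_double_root_boundary(self):
        xs = sorted(s.x for s in fd.fixed_points(0.0, 0.25))
        assert xs == pytest.approx([0.0, 0.5], abs=1e-9)

    def test_quadratic_formula_case(self):
        xs = sorted(s.x for s in fd.fixed_points(0.0, 0.1))
        expect = sorted([0.0, (1 - np.sqrt(0.6)) / 2, (1 + np.sqrt(0.6)) / 2])
        assert xs == pytest.approx(expect, abs=1e-9)

    def test_matches_brute_force_bracketing(self):
        xs = sorted(s.x for s in fd.fixed_points(0.05, 0.3))
        assert xs == pytest.approx(brute_force_roots(0.05, 0.3), abs=1e-6)

    def test_residuals_below_tolerance(self):
        for a, b in [(0.3, 0.9), (-0.2, 0.1), (0.01, 0.02)]:
            for s in fd.fixed_points(a, b):
                assert abs(s.x**3 - s.x**2 + b * s.x + a) < 1e-9

    def test_count_changes_only_across_saddle_node_curve(self):
        grid = np.linspace(-0.3, 1.0, 28)
        for a in grid:
            for b in grid:
                disc = fd.cubic_discriminant(a, b)
                if abs(disc) < 1e-4:
                    continue
                n = len(fd.fixed_points(a, b))
                assert n == (3 if disc > 0 else 1), (a, b, disc, n)


class TestBifurcationSet:
    def test_discriminant_vanishes_on_saddle_node_curves(self):
        bs = fd.bifurcation_set(resolution=150)
        assert bs.saddle_node
        for curve in bs.saddle_node:
            for a, b in curve[::7]:
                assert abs(fd.cubic_discriminant(a, b)) < 1e-8

    def test_hopf_at_origin_fixed_point_requires_zero_pressure(self):
        # x*=0 solves the cubic only when α=0, so that Hopf branch is α=0
        bs = fd.bifurcation_set(resolution=150)
        branch = min(bs.hopf, key=lambda c: np.abs(c[:, 0]).max())
        assert np.all(branch[:, 0] == 0.0)
        assert np.all(branch[:, 1] > 0.0)

    def test_takens_bogdanov_at_curve_intersection(self):
        bs = fd.bifurcation_set(resolution=150)
        a, b = bs.takens_bogdanov
        # double-zero eigenvalue: fixed point x*=0 with zero trace and det
        tr, det = fd.jacobian_trace_det(0.0, b)
        assert abs(fd.cubic_discriminant(a, b)) < 1e-12
        assert tr == 0.0 and det == 0.0

    def test_crossing_hopf_into_region_I_starts_oscillation(self):
        rng = np.random.default_rng(7)
        betas = rng.uniform(0.3, 1.0, 20)
        flips = sum(
            long_sim_oscillates(0.02, b) and not long_sim_oscillates(-0.02, b)
            for b in betas)
        assert flips >= 0.95 * len(betas)

    def test_fine_euler_oracle_agrees_with_rk45_spot_checks(self):
        # one genuine limit cycle, one weakly damped sink that coarse
        # Euler misreads as oscillating
        assert long_sim_oscillates(0.151, 0.895) == rk45_oscillates(0.151, 0.895)
        assert long_sim_oscillates(-0.05, 0.74) == rk45_oscillates(-0.05, 0.74)
        assert not long_sim_oscillates(-0.05, 0.74)

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            fd.bifurcation_set(alpha_range=(1.0, 1.0), resolution=150)


class TestClassifyRegion:
    def test_phee_anchor_is_in_the_calling_region(self):
        assert fd.classify_region(0.151, 0.895).region == "I"

    def test_negative_pressure_single_sink_region(self):
        assert fd.classify_region(-0.1, 0.5).region == "V"

    def test_two_sink_region_exists_below_zero_pressure(self):
        # region IV: two sinks and a saddle at α<0 with small β
        lab = fd.classify_region(-0.01, 0.05)
        kinds = {fd._classify_fp(s.x, 0.05, 45.0)
                 for s in fd.fixed_points(-0.01, 0.05)}
        if kinds == {"sink", "saddle"}:
            assert lab.region == "IV"

    def test_boundary_point_is_flagged(self):
        lab = fd.classify_region(0.0, 0.6)  # exactly on the Hopf curve
        assert lab.boundary


class TestSustainedOscillation:
    def test_all_zero_is_silent(self):
        t = np.arange(0, 300.0, 0.05)
        traj = fd.Trajectory(t, np.zeros_like(t), np.zeros_like(t), 0.05)
        assert not fd.sustained_oscillation(traj)

    def test_decaying_envelope_rejected(self):
        t = np.arange(0, 300.0, 0.05)
        x = np.exp(-t / 40.0) * np.sin(2 * np.pi * t / 3.0)
        traj = fd.Trajectory(t, x, np.gradient(x, t), 0.05)
        assert not fd.sustained_oscillation(traj)

    def test_steady_sinusoid_accepted(self):
        t = np.arange(0, 300.0, 0.05)
        x = np.sin(2 * np.pi * t / 3.0)
        traj = fd.Trajectory(t, x, np.gradient(x, t), 0.05)
        assert fd.sustained_oscillation(traj)
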