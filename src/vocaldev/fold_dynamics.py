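"""Normal-form vocal-fold oscillator and its bifurcation structure.

The vocal folds are modelled as a single-degree-of-freedom oscillator in
normal form,

    dx/dt = y
    dy/dt = -α γ² - β γ² x + γ² x² - γ x y - γ² x³ - γ x² y,

where ``x`` is the nondimensional lateral fold displacement, ``y`` its
velocity, ``α`` the nondimensional lung air pressure, ``β`` the
nondimensional fold tension, and ``γ`` an inverse timescale (1/ms) that
sets the upper range of glottal oscillation frequencies.  Sustained
limit-cycle oscillation of ``x`` is what produces a call.

Fixed points are the real roots of the cubic ``x³ - x² + β x + α = 0``
(with ``y = 0``); the Jacobian there has trace ``-γ x (1 + x)`` and
determinant ``γ² (3x² - 2x + β)``.  Saddle-node bifurcations occur on
the zero set of the cubic's discriminant; Hopf bifurcations occur where
the trace vanishes at a fixed point with positive determinant.  The
(α, β) plane splits into five regions, of which only region I (a unique
unstable equilibrium surrounded by a robust stable limit cycle)
reliably produces calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vocaldev._kernels import BLOWUP_LIMIT, euler_fold

__all__ = [
    "FoldParams",
    "FoldState",
    "Trajectory",
    "ControlSchedule",
    "RegionLabel",
    "BifurcationSet",
    "BlowupError",
    "step_euler",
    "simulate",
    "fixed_points",
    "bifurcation_set",
    "classify_region",
    "sustained_oscillation",
]

#: Control-parameter range in which the normal form is a faithful local
#: reduction of the physical one-mass model; call synthesis is restricted
#: to this box.  Region / fixed-point analysis accepts any real (α, β).
CONTROL_RANGE = (0.0, 1.1)

#: Tolerance on the cubic discriminant for flagging saddle-node boundaries.
DISCRIMINANT_TOL = 1e-8


class BlowupError(RuntimeError):
    """Euler integration produced a non-finite / runaway state (dt too large)."""


@dataclass(frozen=True)
class FoldParams:
    """Control parameters of the fold oscillator.

    alpha : nondimensional lung air pressure.
    beta : nondimensional vocal-fold tension.
    gamma : inverse timescale, 1/ms (default 45).
    """

    alpha: float
    beta: float
    gamma: float = 45.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class FoldState:
    """Lateral fold displacement ``x`` and velocity ``y`` (nondimensional)."""

    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("fold state must be finite")


#: Default initial condition for simulations: a small displacement off the
#: α=0 equilibrium so trajectories reach the attractor quickly.
DEFAULT_INIT = FoldState(0.01, 0.0)


@dataclass
class Trajectory:
    """Uniformly sampled fold trajectory.  Times in ms."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("trajectory arrays must have equal length")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass
class ControlSchedule:
    """Piecewise-linear ramps for α(t) and β(t).

    Each ramp is given as breakpoint times (ms, strictly increasing) and
    values; between breakpoints the control is linearly interpolated, and
    held constant outside the breakpoint range.
    """

    alpha_times: np.ndarray
    alpha_values: np.ndarray
    beta_times: np.ndarray
    beta_values: np.ndarray

    def __post_init__(self) -> None:
        for t, v, name in (
            (self.alpha_times, self.alpha_values, "alpha"),
            (self.beta_times, self.beta_values, "beta"),
        ):
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.ndim != 1 or t.shape != v.shape or len(t) == 0:
                raise ValueError(f"{name} breakpoints malformed")
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} breakpoint times must be strictly increasing")
            lo, hi = CONTROL_RANGE
            if np.any(v < lo) or np.any(v > hi):
                raise ValueError(f"{name} values must lie within {CONTROL_RANGE}")
        self.alpha_times = np.asarray(self.alpha_times, dtype=float)
        self.alpha_values = np.asarray(self.alpha_values, dtype=float)
        self.beta_times = np.asarray(self.beta_times, dtype=float)
        self.beta_values = np.asarray(self.beta_values, dtype=float)

    @classmethod
    def constant(cls, alpha: float, beta: float) -> "ControlSchedule":
        return cls(np.array([0.0]), np.array([alpha]),
                   np.array([0.0]), np.array([beta]))

    @classmethod
    def ramp(cls, times, alpha_values, beta_values) -> "ControlSchedule":
        """Shared breakpoint times for both controls."""
        t = np.asarray(times, dtype=float)
        return cls(t, np.asarray(alpha_values, float),
                   t.copy(), np.asarray(beta_values, float))

    def alpha_at(self, t) -> np.ndarray:
        return np.interp(t, self.alpha_times, self.alpha_values)

    def beta_at(self, t) -> np.ndarray:
        return np.interp(t, self.beta_times, self.beta_values)


@dataclass
class RegionLabel:
    """Dynamical-regime label for a point of the (α, β) plane.

    region : one of "I".."V" (region I is the only calling region).
    dist_saddle_node, dist_hopf : approximate parameter-space distances
        to the nearest saddle-node / Hopf curve.
    boundary : True when the point sits on a bifurcation curve within
        tolerance; the label is then that of the adjacent region with
        larger area.
    """

    region: str
    dist_saddle_node: float
    dist_hopf: float
    boundary: bool = False


@dataclass
class BifurcationSet:
    """Saddle-node and Hopf curves as ordered polylines in (α, β).

    Each polyline is an (n, 2) array of (α, β) points.  The
    Takens-Bogdanov point is the intersection of the two curve families,
    i.e. the parameter point whose fixed point has a double-zero
    eigenvalue.
    """

    saddle_node: list = field(default_factory=list)
    hopf: list = field(default_factory=list)
    takens_bogdanov: tuple = (0.0, 0.0)


# ---------------------------------------------------------------------------
# integration


def _rhs(x: float, y: float, alpha: float, beta: float, gamma: float) -> float:
    return (-alpha * gamma**2 - beta * gamma**2 * x + gamma**2 * x**2
            - gamma * x * y - gamma**2 * x**3 - gamma * x**2 * y)


def step_euler(state: FoldState, params: FoldParams, dt: float = 0.005) -> FoldState:
    """One exact forward-Euler step (no adaptivity).  ``dt`` in ms."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    x1 = state.x + dt * state.y
    y1 = state.y + dt * _rhs(state.x, state.y, params.alpha, params.beta, params.gamma)
    if not (np.isfinite(x1) and np.isfinite(y1) and abs(x1) <= BLOWUP_LIMIT):
        raise BlowupError(
            f"non-finite fold state after Euler step (dt={dt}); reduce dt")
    return FoldState(x1, y1)


def simulate(
    schedule: ControlSchedule | None,
    params: FoldParams,
    duration: float = 1000.0,
    dt: float = 0.005,
    init: FoldState = DEFAULT_INIT,
) -> Trajectory:
    """Integrate the fold oscillator with forward Euler.

    ``schedule`` overrides ``params.alpha`` / ``params.beta`` with
    time-varying piecewise-linear ramps; pass ``None`` to hold the
    controls of ``params`` constant.  ``duration`` and ``dt`` in ms.
    Deterministic given its inputs.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_steps = int(round(duration / dt))
    if n_steps == 0:
        return Trajectory(np.array([0.0]), np.array([init.x]),
                          np.array([init.y]), dt)
    t_steps = np.arange(n_steps) * dt
    if schedule is None:
        alpha = np.full(n_steps, params.alpha)
        beta = np.full(n_steps, params.beta)
    else:
        alpha = np.asarray(schedule.alpha_at(t_steps), dtype=float)
        beta = np.asarray(schedule.beta_at(t_steps), dtype=float)
    x, y, n_valid = euler_fold(alpha, beta, params.gamma, dt, n_steps,
                               init.x, init.y)
    if n_valid < n_steps + 1:
        raise BlowupError(
            f"fold integration blew up at t={n_valid * dt:.3f} ms "
            f"(|x| > {BLOWUP_LIMIT:g}); reduce dt")
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times, x, y, dt)


# ---------------------------------------------------------------------------
# fixed points and bifurcations


def _cubic_coeffs(alpha: float, beta: float) -> np.ndarray:
    # dy/dt = 0 at y = 0  <=>  x³ - x² + βx + α = 0
    return np.array([1.0, -1.0, beta, alpha])


def cubic_discriminant(alpha: float, beta: float):
    """Discriminant of ``x³ - x² + βx + α``; zero on saddle-node curves."""
    return (-18.0 * alpha * beta + 4.0 * alpha + beta**2
            - 4.0 * beta**3 - 27.0 * alpha**2)


def fixed_points(alpha: float, beta: float) -> list[FoldState]:
    """All real equilibria of the fold oscillator, as ``FoldState`` with y=0.

    Roots are polished by Newton iteration to |residual| < 1e-9 and
    deduplicated, so a double root at a saddle-node boundary is reported
    once (count is 1, 2 or 3).
    """
    coeffs = _cubic_coeffs(alpha, beta)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-7].real
    polished = []
    for x0 in real:
        x = x0
        for _ in range(50):
            f = ((x - 1.0) * x + beta) * x + alpha
            df = (3.0 * x - 2.0) * x + beta
            if abs(f) < 1e-12 or df == 0.0:
                break
            x -= f / df
        if abs(((x - 1.0) * x + beta) * x + alpha) < 1e-9:
            polished.append(x)
        else:  # Newton stalled near a repeated root; keep the raw root
            polished.append(x0)
    polished.sort()
    unique: list[float] = []
    for x in polished:
        if not unique or abs(x - unique[-1]) > 1e-6:
            unique.append(x)
    return [FoldState(x, 0.0) for x in unique]


def jacobian_trace_det(x_star: float, beta: float, gamma: float = 45.0):
    """Trace and determinant of the Jacobian at a fixed point (x*, 0)."""
    trace = -gamma * x_star * (1.0 + x_star)
    det = gamma**2 * (3.0 * x_star**2 - 2.0 * x_star + beta)
    return trace, det


def _saddle_node_alpha(beta: float) -> list[float]:
    """α values on the saddle-node curve at a given β (roots of the
    discriminant, which is quadratic in α)."""
    a = -27.0
    b = 4.0 - 18.0 * beta
    c = beta**2 - 4.0 * beta**3
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    s = np.sqrt(disc)
    return sorted(((-b + s) / (2 * a), (-b - s) / (2 * a)))


def bifurcation_set(
    alpha_range: tuple = (-0.4, 1.1),
    beta_range: tuple = (-0.4, 1.1),
    resolution: int = 400,
    gamma: float = 45.0,
) -> BifurcationSet:
    """Saddle-node and Hopf curves over a rectangle of the (α, β) plane.

    The saddle-node curves are the zero set of the cubic discriminant,
    traced as the two α-branches of the quadratic (in α) discriminant
    along a β grid.  The Hopf curves are the loci where the Jacobian at
    a fixed point has zero trace and positive determinant; zero trace
    forces ``x* ∈ {0, -1}``, giving the branches ``α = 0`` (β > 0) and
    ``α = β + 2``.  The Takens-Bogdanov point (double-zero eigenvalue:
    zero trace *and* zero determinant at the same fixed point) is
    reported as the intersection of the curve families.
    """
    if resolution < 100:
        raise ValueError("grid resolution must be at least 100 per axis")
    a_lo, a_hi = alpha_range
    b_lo, b_hi = beta_range
    if not (a_hi > a_lo and b_hi > b_lo):
        raise ValueError("empty parameter range")

    betas = np.linspace(b_lo, b_hi, resolution)
    lower, upper = [], []
    for b in betas:
        sols = _saddle_node_alpha(b)
        if len(sols) == 2:
            if a_lo <= sols[0] <= a_hi:
                lower.append((sols[0], b))
            if a_lo <= sols[1] <= a_hi:
                upper.append((sols[1], b))
    saddle_node = [np.array(p) for p in (lower, upper) if len(p) >= 2]

    hopf = []
    # branch at x* = 0: requires α = 0; det = γ²β > 0 ⇒ β > 0
    bs = betas[betas > 0]
    if a_lo <= 0.0 <= a_hi and len(bs) >= 2:
        hopf.append(np.column_stack([np.zeros_like(bs), bs]))
    # branch at x* = -1: α = β + 2; det = γ²(β + 5) > 0 ⇒ β > -5
    mask = (betas + 2.0 >= a_lo) & (betas + 2.0 <= a_hi) & (betas > -5.0)
    if mask.sum() >= 2:
        hopf.append(np.column_stack([betas[mask] + 2.0, betas[mask]]))

    # TB point: on the x*=0 Hopf branch, det = γ²β → 0 as β → 0, at α = 0.
    return BifurcationSet(saddle_node=saddle_node, hopf=hopf,
                          takens_bogdanov=(0.0, 0.0))


def _distance_to_saddle_node(alpha: float, beta: float) -> float:
    db = 0.2
    betas = np.linspace(beta - db, beta + db, 201)
    best = np.inf
    for b in betas:
        for a in _saddle_node_alpha(b):
            best = min(best, float(np.hypot(a - alpha, b - beta)))
    return best


def _distance_to_hopf(alpha: float, beta: float) -> float:
    d = abs(alpha) if beta > 0 else float(np.hypot(alpha, beta))
    return min(d, abs(alpha - beta - 2.0) / np.sqrt(2.0))


def _classify_fp(x_star: float, beta: float, gamma: float):
    trace, det = jacobian_trace_det(x_star, beta, gamma)
    if det < 0:
        return "saddle"
    if trace < 0:
        return "sink"
    if trace > 0:
        return "source"
    return "center"


def classify_region(
    alpha: float,
    beta: float,
    gamma: float = 45.0,
    *,
    _sim_duration: float = 400.0,
) -> RegionLabel:
    """Assign a point of the (α, β) plane to one of regions I-V.

    Classification uses fixed-point count and stability; regions II and
    III (sink + saddle + source) are disambiguated by short simulation
    from near the source, since region III additionally carries a small
    stable limit cycle.  On a bifurcation curve (within tolerance) the
    adjacent region with larger area is reported and ``boundary`` set.
    """
    disc = cubic_discriminant(alpha, beta)
    d_sn = _distance_to_saddle_node(alpha, beta)
    d_hopf = _distance_to_hopf(alpha, beta)
    on_sn = abs(disc) < DISCRIMINANT_TOL
    on_hopf = d_hopf < 1e-9

    fps = fixed_points(alpha, beta)
    kinds = [_classify_fp(fp.x, beta, gamma) for fp in fps]

    if len(fps) == 1 or on_sn:
        # single equilibrium (or degenerate pair on the SN curve):
        # source ⇒ surrounding limit cycle ⇒ region I; sink ⇒ region V
        kind = kinds[0] if len(fps) == 1 else _classify_fp(
            min(fps, key=lambda f: abs(f.x)).x, beta, gamma)
        if kind == "source":
            region = "I"
        elif kind == "sink":
            region = "V" if alpha <= 0 or on_hopf else "I"
            if alpha > 0 and not on_hopf:
                # right of the Hopf curve a sink can only coexist with
                # boundary effects; verify by simulation
                region = "I" if _oscillates(alpha, beta, gamma, _sim_duration) else "V"
        else:  # center: exactly on the Hopf curve
            region = "V"
            on_hopf = True
        return RegionLabel(region, d_sn, d_hopf, boundary=on_sn or on_hopf)

    if len(fps) == 2:
        # exact saddle-node boundary missed by the discriminant tolerance
        region = "I" if any(k == "source" for k in kinds) else "V"
        return RegionLabel(region, d_sn, d_hopf, boundary=True)

    n_sinks = kinds.count("sink")
    if n_sinks == 2:
        return RegionLabel("IV", d_sn, d_hopf, boundary=on_sn or on_hopf)
    # sink + saddle + source: region II (no limit cycle) or III (small
    # stable cycle around the source); decide by simulation from the source
    src = fps[int(np.argmax([k == "source" for k in kinds]))]
    osc = _oscillates(alpha, beta, gamma, _sim_duration,
                      init=FoldState(src.x + 1e-3, 0.0))
    region = "III" if osc else "II"
    return RegionLabel(region, d_sn, d_hopf, boundary=on_sn or on_hopf)


def _oscillates(alpha, beta, gamma, duration, init=DEFAULT_INIT) -> bool:
    try:
        traj = simulate(None, FoldParams(alpha, beta, gamma),
                        duration=duration, dt=0.005, init=init)
    except BlowupError:
        return False
    return sustained_oscillation(traj, transient_ms=duration / 2)


def sustained_oscillation(
    traj: Trajectory,
    transient_ms: float = 100.0,
    amp_threshold: float = 1e-3,
) -> bool:
    """True iff the post-transient displacement is a non-decaying oscillation.

    Requires post-transient peak-to-peak amplitude above
    ``amp_threshold`` and the last-quarter amplitude to be at least 90%
    of the second-quarter amplitude (quarters of the post-transient
    window), which rejects slowly decaying transients.
    """
    total_ms = traj.times[-1] - traj.times[0]
    if total_ms <= transient_ms:
        raise ValueError("trajectory shorter than the transient window")
    x = traj.x[traj.times >= traj.times[0] + transient_ms]
    if len(x) < 8:
        return False
    if np.ptp(x) <= amp_threshold:
        return False
    q = len(x) // 4
    amp_second = np.ptp(x[q:2 * q])
    amp_last = np.ptp(x[3 * q:])
    if amp_second <= amp_threshold:
        return False
    return amp_last >= 0.9 * amp_second
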