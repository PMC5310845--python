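"""The optimal-control core: cost landscapes, softmax selection, development.

The cost of producing a call at control value θ on postnatal day t is

    C_t(θ) = −log g_t(θ) + λ0 θ − δ t θ − κ F t θ,

whose terms are: the biomechanical term −log g_t(θ) (high acoustic gain
= low cost; troughs move as the vocal tract lengthens), the muscular
effort λ θ with coefficient λ_t = λ0 − (κF + δ) t that decays daily by
a feedback-driven learning part κF and a feedback-independent
maturation part δ, where F ∈ [0, 1] is the proportion of infant calls
receiving a contingent parental response.

Call production follows the maximum-entropy (softmax) rule
p(θ) = exp(−η C(θ))/Z; call-type probabilities integrate p over the
labelled regions of the gain landscape (right Riemann sums throughout),
and the phee/cry ratio (P_phee − P_cry)/(P_phee + P_cry) summarises the
developmental transition.  The day the model ratio crosses zero defines
λ_z, and the closed form z0 = (λ0 − λ_z)/(κF + δ) links the transition
day to parental feedback.

The softmax density is also the stationary law of an overdamped
Langevin diffusion on θ with drift −∂C/∂θ and noise scale √(2/η);
``diffusion_simulate`` runs that walk for visualisation and equilibrium
checks.  (The drift sign is chosen so that the stationary density is
exp(−ηC)/Z; a gradient *ascent* drift would concentrate the walk on
cost maxima instead.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from vocaldev._kernels import langevin_walk
from vocaldev.call_catalog import GainLandscape

__all__ = [
    "CostLandscape",
    "SoftmaxDensity",
    "DevelopmentParams",
    "DiffusionRun",
    "KappaDeltaFit",
    "cost_basic",
    "cost_muscular",
    "lambda_at",
    "cost_full",
    "softmax_density",
    "call_probabilities",
    "phee_cry_ratio",
    "model_phee_cry_ratio",
    "solve_lambda_z",
    "fit_lambda_daily",
    "predict_zero_crossing",
    "fit_kappa_delta",
    "diffusion_simulate",
]

#: Default softmax concentration for the full developmental model; the
#: sharp cry→phee transition needs a strongly concentrated density.
ETA_FULL = 300.0
#: Default concentration when fitting a daily λ to ratio data, where a
#: diffuse density keeps the λ→ratio map well-conditioned.
ETA_DAILY = 5.0
#: Initial muscular-effort coefficient.  Any λ0 > λ_z produces the same
#: fitted curves up to rescaling of (κ, δ); it is a convention, not a
#: data-estimable quantity.
LAMBDA0 = 3.0


@dataclass(frozen=True)
class DevelopmentParams:
    """Developmental parameters of the muscular-effort coefficient.

    lambda0 : initial effort coefficient at day 0.
    kappa : feedback-driven (learning) decay rate, 1/day.
    delta : feedback-independent maturation decay rate, 1/day.
    F : proportion of calls receiving a contingent parental response.
    """

    lambda0: float = LAMBDA0
    kappa: float = 0.2126
    delta: float = 0.0654
    F: float = 0.122

    def __post_init__(self) -> None:
        if min(self.lambda0, self.kappa, self.delta, self.F) < 0:
            raise ValueError("development parameters must be non-negative")
        if self.F > 1:
            raise ValueError("F is a proportion and must be <= 1")


@dataclass
class CostLandscape:
    """Cost C(θ) on a θ grid; +inf on cells that produce no call."""

    theta: np.ndarray
    C: np.ndarray
    labels: np.ndarray
    day: float | None = None
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.theta) == len(self.C) == len(self.labels)):
            raise ValueError("cost landscape grids must be aligned")


@dataclass
class SoftmaxDensity:
    """Probability density over θ with right-Riemann normalisation.

    Each grid point θ_i is the right endpoint of a cell of width h, so
    integrals are ``h * sum(p_i)`` and the density normalises to
    ``sum(p) * h == 1``.
    """

    theta: np.ndarray
    p: np.ndarray
    eta: float
    Z: float

    @property
    def h(self) -> float:
        return float(self.theta[1] - self.theta[0])

    def integral(self, mask=None) -> float:
        w = self.p if mask is None else self.p * mask
        return float(w.sum() * self.h)


# ---------------------------------------------------------------------------
# costs


def cost_basic(gl: GainLandscape) -> CostLandscape:
    """Biomechanical cost C(θ) = −log g(θ); +inf where no call exists."""
    voiced = gl.labels != "none"
    if np.any(~(gl.g[voiced] > 0)):
        raise ValueError("labelled landscape cell with non-positive gain")
    C = np.full(len(gl.theta), np.inf)
    C[voiced] = -np.log(gl.g[voiced])
    return CostLandscape(gl.theta.copy(), C, gl.labels.copy(),
                         components={"neg_log_gain": C.copy()})


def cost_muscular(gl: GainLandscape, lam: float) -> CostLandscape:
    """Cost with muscular effort: C(θ) = −log g(θ) + λ θ."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    base = cost_basic(gl)
    C = base.C + lam * gl.theta
    comp = {"neg_log_gain": base.components["neg_log_gain"],
            "lambda_theta": lam * gl.theta}
    return CostLandscape(gl.theta.copy(), C, gl.labels.copy(), components=comp)


def lambda_at(t: float, p: DevelopmentParams) -> float:
    """λ_t = λ0 − (κF + δ) t, clipped at 0 (with a warning) once the
    linear decay would go negative."""
    if t < 0:
        raise ValueError("postnatal day must be non-negative")
    lam = p.lambda0 - (p.kappa * p.F + p.delta) * t
    if lam < 0:
        warnings.warn(f"lambda reached 0 before day {t:g}; clipping",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(lam)


def cost_full(gl_t: GainLandscape, p: DevelopmentParams, t: float) -> CostLandscape:
    """Day-t developmental cost C_t(θ) = −log g_t(θ) + λ_t θ.

    ``gl_t`` must be built with the day-t tract delay; the tract-growth
    effect enters through it (trough shift), while δ·t·θ (rotation) and
    κ·F·t·θ (feedback tilt) are folded into λ_t.
    """
    cl = cost_muscular(gl_t, lambda_at(t, p))
    cl.day = t
    return cl


# ---------------------------------------------------------------------------
# softmax and probabilities


def softmax_density(C: CostLandscape, eta: float) -> SoftmaxDensity:
    """Maximum-entropy density p(θ) = exp(−η C(θ)) / Z.

    Z is a right Riemann sum over the grid; infinite-cost cells carry
    zero probability.  η = 0 yields the uniform density over the
    finite-cost support.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    finite = np.isfinite(C.C)
    if not finite.any():
        raise ValueError("all cells have infinite cost; density undefined")
    h = float(C.theta[1] - C.theta[0])
    w = np.zeros(len(C.theta))
    cmin = C.C[finite].min()
    w[finite] = np.exp(-eta * (C.C[finite] - cmin))
    Z = float(w.sum() * h)
    return SoftmaxDensity(C.theta.copy(), w / Z, eta, Z * np.exp(-eta * cmin))


def call_probabilities(d: SoftmaxDensity, labels: np.ndarray):
    """(P_cry, P_subharmonic, P_phee): right-Riemann integrals of the
    density over each labelled region."""
    if len(labels) != len(d.theta):
        raise ValueError("labels must align with the density grid")
    return tuple(d.integral(labels == lab)
                 for lab in ("cry", "subharmonic_phee", "phee"))


def phee_cry_ratio(p_phee: float, p_cry: float) -> float:
    """(P_phee − P_cry) / (P_phee + P_cry), in [−1, 1]."""
    tot = p_phee + p_cry
    if tot <= 0:
        raise ValueError("phee/cry ratio undefined: both probabilities zero")
    return (p_phee - p_cry) / tot


def model_phee_cry_ratio(gl: GainLandscape, lam: float, eta: float) -> float:
    """Ratio implied by the muscular cost at (λ, η)."""
    d = softmax_density(cost_muscular(gl, lam), eta)
    p_cry, _, p_phee = call_probabilities(d, gl.labels)
    return phee_cry_ratio(p_phee, p_cry)


def solve_lambda_z(
    gl: GainLandscape,
    eta: float = ETA_FULL,
    bracket: tuple = (0.0, LAMBDA0),
    tol: float = 1e-6,
) -> float:
    """λ at which the model's phee and cry probabilities are equal.

    Bisection on the (monotone-decreasing) λ → ratio map until the
    ratio magnitude falls below ``tol``.
    """
    lo, hi = bracket
    f_lo, f_hi = (model_phee_cry_ratio(gl, v, eta) for v in (lo, hi))
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no zero crossing in lambda bracket {bracket}: "
            f"ratio({lo})={f_lo:.3f}, ratio({hi})={f_hi:.3f}")
    while True:
        mid = 0.5 * (lo + hi)
        f_mid = model_phee_cry_ratio(gl, mid, eta)
        if abs(f_mid) < tol or hi - lo < 1e-12:
            return mid
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid


def fit_lambda_daily(
    days: np.ndarray,
    ratios: np.ndarray,
    gl: GainLandscape,
    eta: float = ETA_DAILY,
    lam_max: float = 20.0,
) -> np.ndarray:
    """Per-day λ best matching an observed phee/cry ratio curve.

    For each day, solves model_ratio(λ) = ratio by root finding on the
    monotone λ → ratio map; target ratios outside the model's attainable
    range are clamped to the nearest endpoint with a warning.
    """
    days = np.asarray(days, float)
    ratios = np.asarray(ratios, float)
    r_hi = model_phee_cry_ratio(gl, 0.0, eta)
    r_lo = model_phee_cry_ratio(gl, lam_max, eta)
    out = np.empty(len(days))
    for i, r in enumerate(ratios):
        if r >= r_hi:
            if r > r_hi + 1e-12:
                warnings.warn(f"day {days[i]:g}: ratio {r:.3f} above model "
                              f"range; clamping lambda to 0", RuntimeWarning,
                              stacklevel=2)
            out[i] = 0.0
        elif r <= r_lo:
            if r < r_lo - 1e-12:
                warnings.warn(f"day {days[i]:g}: ratio {r:.3f} below model "
                              f"range; clamping lambda to {lam_max}",
                              RuntimeWarning, stacklevel=2)
            out[i] = lam_max
        else:
            out[i] = brentq(lambda lam: model_phee_cry_ratio(gl, lam, eta) - r,
                            0.0, lam_max, xtol=1e-10)
    return out


# ---------------------------------------------------------------------------
# developmental fits


def predict_zero_crossing(p: DevelopmentParams, lambda_z: float) -> float:
    """Zero-crossing day z0 = (λ0 − λ_z) / (κF + δ); inf when the
    denominator vanishes (no development)."""
    denom = p.kappa * p.F + p.delta
    if p.lambda0 <= lambda_z:
        raise ValueError("lambda0 must exceed lambda_z for a crossing to exist")
    if denom == 0:
        return float("inf")
    return (p.lambda0 - lambda_z) / denom


@dataclass
class KappaDeltaFit:
    """Nonlinear least-squares fit of z0 = (λ0 − λ_z)/(κF + δ)."""

    kappa: float
    delta: float
    residuals: np.ndarray
    kappa_identifiable: bool

    def predict(self, F, lambda0: float = LAMBDA0, lambda_z: float = 0.7927):
        F = np.asarray(F, float)
        return (lambda0 - lambda_z) / (self.kappa * F + self.delta)


def fit_kappa_delta(
    F: np.ndarray,
    z0: np.ndarray,
    lambda0: float = LAMBDA0,
    lambda_z: float = 0.7927,
) -> KappaDeltaFit:
    """Estimate (κ, δ) ≥ 0 from per-infant (F, z0) pairs.

    Nonlinear least squares on z0 = A/(κF + δ) with A = λ0 − λ_z,
    initialised from the exact linearisation A/z0 = κF + δ.  With no
    spread in F the two rates are not separable and the fit raises; with
    all F = 0, κ is structurally unidentifiable and reported as NaN.
    """
    F = np.asarray(F, float)
    z0 = np.asarray(z0, float)
    if len(F) != len(z0) or len(F) < 2:
        raise ValueError("need at least two (F, z0) pairs")
    if np.any(z0 <= 0):
        raise ValueError("zero-crossing days must be positive")
    A = lambda0 - lambda_z
    if np.ptp(F) == 0:
        if np.all(F == 0):
            delta = float(np.mean(A / z0))
            res = z0 - A / delta
            return KappaDeltaFit(float("nan"), delta, res,
                                 kappa_identifiable=False)
        raise ValueError("degenerate design: all F values identical")
    # exact solution of the linearised problem as the starting point
    y = A / z0
    slope, intercept = np.polyfit(F, y, 1)
    x0 = np.array([max(slope, 1e-6), max(intercept, 1e-6)])
    sol = least_squares(lambda p: z0 - A / (p[0] * F + p[1]), x0,
                        bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-15,
                        ftol=1e-15, gtol=1e-15)
    kappa, delta = sol.x
    return KappaDeltaFit(float(kappa), float(delta), sol.fun,
                         kappa_identifiable=True)


# ---------------------------------------------------------------------------
# diffusion


@dataclass
class DiffusionRun:
    """Langevin-walk realisation over a (possibly day-varying) landscape.

    theta_by_day : visited positions per simulated day.
    emissions_by_day : θ values sampled at the call-emission interval.
    labels_by_day : call-type label of each emission (nearest grid cell).
    """

    theta_by_day: list
    emissions_by_day: list
    labels_by_day: list
    eta: float
    step_dt: float
    seed: int | None

    def daily_counts(self) -> "np.ndarray":
        import pandas as pd

        rows = []
        for day, labs in enumerate(self.labels_by_day):
            labs = np.asarray(labs)
            rows.append({
                "day": day,
                "n_cry": int((labs == "cry").sum()),
                "n_subharmonic": int((labs == "subharmonic_phee").sum()),
                "n_phee": int((labs == "phee").sum()),
            })
        return pd.DataFrame(rows)


def _finite_support(C: CostLandscape):
    finite = np.isfinite(C.C)
    if not finite.any():
        raise ValueError("cost landscape has no finite support")
    # largest contiguous finite block
    idx = np.flatnonzero(finite)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    block = max(splits, key=len)
    return block[0], block[-1]


def diffusion_simulate(
    costs: list[CostLandscape] | CostLandscape,
    eta: float,
    steps_per_day: int = 200_000,
    step_dt: float = 1e-4,
    seed: int | None = None,
    record_every: int = 1,
    emission_every: int = 2000,
    theta0: float | None = None,
) -> DiffusionRun:
    """Random-walk approximation of the landscape diffusion.

    Each simulated day runs ``steps_per_day`` Euler-Maruyama steps of
    dθ = −C'(θ) dt + √(2/η) dW on that day's cost landscape (central-
    difference gradient, one-sided at the edges), reflecting at the
    edges of the finite-cost support.  Positions are recorded every
    ``record_every`` steps; emissions are the walk sampled every
    ``emission_every`` *recorded* positions, mimicking the roughly
    once-per-second call production of infant marmosets.  A step size
    rejected by the blow-up guard (>50% of moves leaving the domain)
    raises.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if isinstance(costs, CostLandscape):
        costs = [costs]
    seed_seq = np.random.SeedSequence(seed)
    day_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in seed_seq.spawn(len(costs))]
    noise_scale = np.sqrt(2.0 * step_dt / eta)
    theta_by_day, emissions_by_day, labels_by_day = [], [], []
    th = theta0
    for C, day_seed in zip(costs, day_seeds):
        i0, i1 = _finite_support(C)
        grid = C.theta[i0:i1 + 1]
        vals = C.C[i0:i1 + 1]
        grad = np.gradient(vals, grid)
        lo, hi = float(grid[0]), float(grid[-1])
        if th is None or not (lo <= th <= hi):
            th = 0.5 * (lo + hi)
        walk, th_end, n_out = langevin_walk(th, grad, grid, lo, hi, step_dt,
                                            noise_scale, steps_per_day,
                                            record_every, day_seed)
        if n_out > 0.5 * steps_per_day:
            raise ValueError("diffusion step size too large: most moves "
                             "rejected by the domain guard")
        th = float(th_end)
        theta_by_day.append(walk)
        em = walk[emission_every::emission_every]
        emissions_by_day.append(em)
        cell = np.clip(np.searchsorted(C.theta, em), 0, len(C.theta) - 1)
        labels_by_day.append(C.labels[cell])
    return DiffusionRun(theta_by_day, emissions_by_day, labels_by_day,
                        eta, step_dt, seed)
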