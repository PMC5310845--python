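"""Synthetic cohorts and audio fixtures with known ground truth.

The generator samples from the landscape model itself: per postnatal
day it builds the day's cost landscape, converts it to call-type
probabilities through the softmax rule, and draws per-session call
counts multinomially.  Dominant frequencies follow the day's tract
resonance, parental contingent responses are Bernoulli in the infant's
feedback probability F, and weights grow linearly with noise.  Every
generated quantity is recorded in a per-infant truth record so that
recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vocaldev import audio as _audio
from vocaldev.call_catalog import (
    CRY_ANCHOR,
    PHEE_ANCHOR,
    GainLandscape,
    default_theta_grid,
    gain_landscape,
)
from vocaldev.landscape import (
    DevelopmentParams,
    call_probabilities,
    cost_full,
    softmax_density,
    predict_zero_crossing,
    solve_lambda_z,
)
from vocaldev.tract_filter import TractParams, resonance_frequency

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_infant",
    "generate_cohort",
    "generate_audio_session",
    "landscape_cache",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    The defaults mirror the study conditions: 10 infants followed over
    postnatal days 0-60, one 5-minute undirected session per day with
    calls emitted at roughly one per second (Poisson mean 300 per
    session), a vocal tract whose one-way travel time lengthens in
    three stages (40 → 45 → 50 μs, the landscape-shift values used for
    the developmental figures), λ0 = 3, learning rate κ = 0.2126 /day,
    maturation rate δ = 0.0654 /day, and per-infant feedback proportions
    F drawn uniformly from [0.05, 0.3].

    The generation-side softmax concentration defaults to η = 5, the
    value used when fitting daily effort coefficients to ratio data: at
    the full-landscape η = 300 the subharmonic trough captures
    essentially all probability mass through mid-development, so phees
    and cries become unobservably rare in finite sessions and the
    empirical ratio curve cannot express the transition.  A diffuse
    concentration keeps all three call types observable, as in the
    measured cohort.
    """

    n_infants: int = 10
    days: tuple = tuple(range(0, 61))
    sessions_per_day: int = 1
    calls_per_session_mean: float = 300.0
    lambda0: float = 3.0
    kappa: float = 0.2126
    delta: float = 0.0654
    F_range: tuple = (0.05, 0.3)
    eta: float = 5.0
    #: (day_from, half_T_us) stages of tract growth, in ascending order.
    half_T_stages: tuple = ((0, 40.0), (21, 45.0), (41, 50.0))
    dom_freq_noise_khz: float = 0.2
    weight0_g: float = 30.0
    weight_rate_g_per_day: float = 1.0
    weight_noise_g: float = 0.5
    weight_every_days: int = 3
    gamma: float = 45.0
    dt_us: float = 5.0
    theta_n: int = 221
    call_duration_ms: float = 1000.0

    def half_T_at(self, day: float) -> float:
        out = self.half_T_stages[0][1]
        for d0, ht in self.half_T_stages:
            if day >= d0:
                out = ht
        return out


@dataclass
class SyntheticCohort:
    """Session table plus per-infant truth records and config echo."""

    sessions: pd.DataFrame
    truth: dict
    config: CohortConfig
    master_seed: int | None = None


def landscape_cache(cfg: CohortConfig) -> dict[float, GainLandscape]:
    """Gain landscape for each distinct tract stage of a config."""
    theta = default_theta_grid(cfg.theta_n)
    cache: dict[float, GainLandscape] = {}
    for _, half_T in cfg.half_T_stages:
        if half_T not in cache:
            tract = TractParams(half_T=half_T, dt=cfg.dt_us)
            cache[half_T] = gain_landscape(
                theta, cfg.gamma, tract, duration_ms=cfg.call_duration_ms)
    return cache


def generate_infant(
    cfg: CohortConfig,
    infant_seed: int,
    infant_id: str = "inf0",
    landscapes: dict[float, GainLandscape] | None = None,
    F: float | None = None,
):
    """Simulate one infant's longitudinal sessions.

    Returns ``(sessions, truth)``: a per-session DataFrame (day, call
    counts, parental responses, dominant frequency, weight) and a truth
    record with the infant's development parameters, per-day λ and call
    probabilities, and the model-predicted zero-crossing day.
    """
    rng = np.random.default_rng(infant_seed)
    if landscapes is None:
        landscapes = landscape_cache(cfg)
    if F is None:
        F = float(rng.uniform(*cfg.F_range))
    dev = DevelopmentParams(cfg.lambda0, cfg.kappa, cfg.delta, F)
    # The zero-crossing prediction must use the λ_z of the tract stage in
    # force on the crossing day.  Walk the stages in order: the crossing
    # is either interior to a stage (λ_t hits that stage's λ_z) or occurs
    # exactly at a stage boundary (λ_z jumps above the current λ_t there).
    stage_days = [d0 for d0, _ in cfg.half_T_stages] + [max(cfg.days) + 1]
    lambda_z = None
    z0_pred = None
    for (d0, half_T), d1 in zip(cfg.half_T_stages, stage_days[1:]):
        lz = solve_lambda_z(landscapes[half_T], eta=cfg.eta,
                            bracket=(0.0, cfg.lambda0))
        z = predict_zero_crossing(dev, lz)
        lambda_z = lz
        if z < d0:       # λ already below this stage's λ_z at stage entry
            z0_pred = float(d0)
            break
        if z < d1:       # interior crossing
            z0_pred = z
            break
    if z0_pred is None:  # never crosses within the observed window
        z0_pred = predict_zero_crossing(dev, lambda_z)

    rows = []
    lam_by_day, probs_by_day = {}, {}
    weight = cfg.weight0_g
    last_weight_day = cfg.days[0]
    import warnings as _warnings

    for day in cfg.days:
        gl = landscapes[cfg.half_T_at(day)]
        with _warnings.catch_warnings():
            # λ_t hitting its floor late in development is expected here
            _warnings.simplefilter("ignore", RuntimeWarning)
            C = cost_full(gl, dev, day)
        d = softmax_density(C, cfg.eta)
        p_cry, p_sub, p_phee = call_probabilities(d, gl.labels)
        tot = p_cry + p_sub + p_phee
        p = np.array([p_cry, p_sub, p_phee]) / tot
        lam_by_day[day] = C.components["lambda_theta"][-1] / gl.theta[-1]
        probs_by_day[day] = p
        f0 = resonance_frequency(TractParams(half_T=cfg.half_T_at(day),
                                             dt=cfg.dt_us))
        weight = (cfg.weight0_g + cfg.weight_rate_g_per_day * day
                  + rng.normal(0.0, cfg.weight_noise_g))
        measure_weight = (day - last_weight_day >= cfg.weight_every_days
                          or day == cfg.days[0])
        if measure_weight:
            last_weight_day = day
        for _ in range(cfg.sessions_per_day):
            n_calls = rng.poisson(cfg.calls_per_session_mean)
            n_cry, n_sub, n_phee = rng.multinomial(n_calls, p)
            n_contingent = rng.binomial(n_phee, F) if n_phee else 0
            rows.append({
                "infant_id": infant_id,
                "day": day,
                "n_cry": int(n_cry),
                "n_subharmonic": int(n_sub),
                "n_phee": int(n_phee),
                "n_parent_contingent": int(n_contingent),
                "dom_freq_khz": float(f0 + rng.normal(0.0, cfg.dom_freq_noise_khz)),
                "weight_g": float(weight) if measure_weight else np.nan,
            })
    sessions = pd.DataFrame(rows)
    truth = {
        "infant_id": infant_id,
        "seed": infant_seed,
        "F": F,
        "kappa": cfg.kappa,
        "delta": cfg.delta,
        "lambda0": cfg.lambda0,
        "lambda_z": lambda_z,
        "z0_pred": z0_pred,
        "lambda_by_day": lam_by_day,
        "probs_by_day": probs_by_day,
        "half_T_by_day": {d: cfg.half_T_at(d) for d in cfg.days},
    }
    return sessions, truth


def generate_cohort(cfg: CohortConfig, master_seed: int) -> SyntheticCohort:
    """Generate a full cohort, deterministic in the master seed.

    Per-infant seeds are spawned from the master seed; the shared gain
    landscapes are computed once per tract stage.
    """
    landscapes = landscape_cache(cfg)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(cfg.n_infants)
    frames, truth = [], {}
    for i, child in enumerate(children):
        infant_id = f"inf{i}"
        seed = int(child.generate_state(1)[0] % (2**31))
        s, t = generate_infant(cfg, seed, infant_id, landscapes)
        frames.append(s)
        truth[infant_id] = t
    sessions = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=[
                    "infant_id", "day", "n_cry", "n_subharmonic", "n_phee",
                    "n_parent_contingent", "dom_freq_khz", "weight_g"]))
    return SyntheticCohort(sessions, truth, cfg, master_seed)


#: Constant-control anchors used for audio fixtures, per call type.
_AUDIO_ANCHORS = {"cry": CRY_ANCHOR, "phee": PHEE_ANCHOR}


def generate_audio_session(
    schedule,
    fs: int = 96_000,
    tract: TractParams | None = None,
    gamma: float = 45.0,
    snr_db: float = 20.0,
    duration_s: float | None = None,
    call_duration_s: float = 1.0,
    seed: int | None = None,
):
    """Render a session recording: scheduled calls over pink noise.

    ``schedule`` is a list of ``(onset_s, call_type)`` with call_type in
    {"cry", "phee"}; calls are synthesized at the model sampling rate
    from the per-type anchor parameters, resampled to ``fs``, placed at
    their onsets over a pink-noise background at ``snr_db``, and
    returned with a truth table (onset_s, offset_s, call_type).
    Overlapping schedule entries raise.
    """
    from vocaldev.call_catalog import synthesize_call

    tract = tract if tract is not None else TractParams()
    sched = sorted(schedule, key=lambda e: e[0])
    for (t0, _), (t1, _) in zip(sched, sched[1:]):
        if t1 < t0 + call_duration_s:
            raise ValueError("scheduled calls overlap")
    if duration_s is None:
        duration_s = (sched[-1][0] + call_duration_s + 1.0) if sched else 10.0
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    noise = _audio.pink_noise(n, rng)
    audio = np.zeros(n)
    fs_model = 1e6 / tract.dt
    rows = []
    for onset, ctype in sched:
        if ctype not in _AUDIO_ANCHORS:
            raise ValueError(f"unsupported audio call type {ctype!r}")
        a, b = _AUDIO_ANCHORS[ctype]
        w = synthesize_call(a, b, tract=tract,
                            duration_ms=call_duration_s * 1e3)
        call = _audio.resample(w.p_sound, fs_model, fs)
        call = call / np.max(np.abs(call))
        i0 = int(round(onset * fs))
        i1 = min(i0 + len(call), n)
        audio[i0:i1] += call[:i1 - i0]
        rows.append({"onset_s": onset, "offset_s": onset + call_duration_s,
                     "call_type": ctype})
    sig_rms = np.sqrt(np.mean(audio**2)) if sched else 1.0
    noise_rms = np.sqrt(np.mean(noise**2))
    # scale noise to the requested SNR relative to the call segments
    if sched:
        seg = np.concatenate([
            audio[int(r["onset_s"] * fs):int(r["offset_s"] * fs)] for r in rows])
        sig_rms = np.sqrt(np.mean(seg**2))
    audio = audio + noise * sig_rms / noise_rms * 10 ** (-snr_db / 20.0)
    return audio, pd.DataFrame(rows)
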