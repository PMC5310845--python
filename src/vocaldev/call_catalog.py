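"""Call synthesis over control-parameter space and call-type classification.

A call is synthesised by driving the fold oscillator with (optionally
ramped) control parameters and passing the displacement through the
tract filter.  Synthesised calls fall into four classes:

``cry``
    slow glottal pulsing far below the tract resonance; the resonator
    rings at every pulse, producing a strongly amplitude-modulated,
    noisy-sounding call.  Detected by the modulation depth of the
    Hilbert envelope.
``subharmonic_phee``
    glottal oscillation at an intermediate frequency whose *harmonics*
    (not the fundamental) fall on the resonance, so the dominant
    spectral peak is not the lowest one.
``phee``
    tonal call with the fundamental itself near the resonance: the
    first (lowest-frequency) spectral peak is the largest.
``none``
    no sustained fold oscillation.

The gain landscape along the diagonal α = β = θ is the biomechanical
layer of the developmental cost landscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from vocaldev import audio as _audio
from vocaldev.fold_dynamics import (
    ControlSchedule,
    DEFAULT_INIT,
    FoldParams,
    FoldState,
    Trajectory,
    simulate,
    sustained_oscillation,
)
from vocaldev.tract_filter import SoundWaveforms, TractParams, filter_glottal, gain

__all__ = [
    "CALL_LABELS",
    "CRY_ANCHOR",
    "PHEE_ANCHOR",
    "ClassifierConfig",
    "GainLandscape",
    "FrequencyAmplitudeMaps",
    "synthesize_call",
    "classify_call",
    "gain_landscape",
    "frequency_amplitude_maps",
    "default_theta_grid",
]

CALL_LABELS = ("none", "cry", "subharmonic_phee", "phee")

#: Constant-control anchor parameters that reproduce the two call
#: morphologies used to validate the classifier: a cry and a phee.
CRY_ANCHOR = (0.09364, 0.088)
PHEE_ANCHOR = (0.151, 0.895)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the model-call classifier.

    transient_ms : initial window excluded from all measurements (limit
        cycle convergence).
    amp_threshold : minimal post-transient peak-to-peak displacement for
        a call to count as voiced.
    envelope_lowpass_khz : cutoff applied to the Hilbert envelope before
        measuring amplitude modulation.
    modulation_threshold : std/mean of the lowpassed envelope above
        which a call is a cry (calibrated so the cry and phee anchor
        parameters classify correctly; cry anchor ≈ 0.33, phee ≈ 0.002).
    peak_rel_height : spectral peaks must exceed this fraction of the
        tallest peak.
    peak_min_sep_hz : minimal separation between spectral peaks.
    """

    transient_ms: float = 100.0
    amp_threshold: float = 1e-3
    envelope_lowpass_khz: float = 4.0
    modulation_threshold: float = 0.1
    peak_rel_height: float = 0.01
    peak_min_sep_hz: float = 200.0


def default_theta_grid(n: int = 221) -> np.ndarray:
    """Diagonal grid θ ∈ [0, 1.1]; 221 points give a 0.005 step, fine
    enough to resolve the narrow cry band above the saddle-node onset."""
    return np.linspace(0.0, 1.1, n)


def synthesize_call(
    alpha_ramp,
    beta_ramp,
    fold: FoldParams | None = None,
    tract: TractParams | None = None,
    duration_ms: float = 1000.0,
    init: FoldState = DEFAULT_INIT,
    add_pink_noise: bool = False,
    snr_db: float = 20.0,
    seed: int | None = None,
) -> SoundWaveforms:
    """Synthesise one call: fold simulation composed with the tract filter.

    ``alpha_ramp`` / ``beta_ramp`` may be constants or ``(times_ms,
    values)`` breakpoint pairs for piecewise-linear ramps.  With
    ``add_pink_noise`` a 1/f-spectrum background is added to the emitted
    sound at ``snr_db``; without it the output is bit-reproducible.
    """
    gamma = fold.gamma if fold is not None else 45.0
    tract = tract if tract is not None else TractParams()
    sched = _as_schedule(alpha_ramp, beta_ramp)
    dt_ms = tract.dt * 1e-3
    traj = simulate(sched, FoldParams(0.0, 0.0, gamma), duration=duration_ms,
                    dt=dt_ms, init=init)
    w = filter_glottal(traj.x, tract)
    if add_pink_noise:
        rng = np.random.default_rng(seed)
        noise = _audio.pink_noise(len(w.p_sound), rng)
        w = SoundWaveforms(w.p_glottal, w.p_in,
                           _audio.mix_at_snr(w.p_sound, noise, snr_db), w.dt)
    return w


def _as_schedule(alpha_ramp, beta_ramp) -> ControlSchedule:
    def parse(ramp):
        if np.isscalar(ramp):
            return np.array([0.0]), np.array([float(ramp)])
        t, v = ramp
        return np.asarray(t, float), np.asarray(v, float)

    at, av = parse(alpha_ramp)
    bt, bv = parse(beta_ramp)
    return ControlSchedule(at, av, bt, bv)


# ---------------------------------------------------------------------------
# classification


def _envelope_modulation(seg: np.ndarray, fs_hz: float,
                         cfg: ClassifierConfig) -> float:
    env = np.abs(sps.hilbert(seg))
    sos = sps.butter(4, cfg.envelope_lowpass_khz * 1e3, fs=fs_hz, output="sos")
    env_low = sps.sosfiltfilt(sos, env)
    mean = env_low.mean()
    if mean <= 0:
        return 0.0
    return float(env_low.std() / mean)


def _spectral_peaks(seg: np.ndarray, fs_hz: float, cfg: ClassifierConfig):
    s = seg - seg.mean()
    spec = np.abs(np.fft.rfft(s * np.hanning(len(s)))) ** 2
    freqs = np.fft.rfftfreq(len(s), 1.0 / fs_hz)
    df = freqs[1] - freqs[0]
    dist = max(1, int(round(cfg.peak_min_sep_hz / df)))
    idx, _ = sps.find_peaks(spec, height=cfg.peak_rel_height * spec.max(),
                            distance=dist)
    return freqs[idx], spec[idx]


def classify_call(
    w: SoundWaveforms,
    cfg: ClassifierConfig = ClassifierConfig(),
    traj: Trajectory | None = None,
) -> str:
    """Classify a synthesised call as cry / subharmonic_phee / phee / none.

    ``none`` when the post-transient glottal signal is not a sustained
    oscillation; ``cry`` when the (4-kHz-lowpassed) Hilbert envelope of
    the emitted sound is strongly modulated; otherwise ``phee`` when the
    first spectral peak of the call is also its largest, else
    ``subharmonic_phee``.
    """
    i0 = int(round(cfg.transient_ms * 1e3 / w.dt))
    if i0 >= len(w.p_sound):
        raise ValueError("call shorter than the classifier transient window")
    pg = w.p_glottal[i0:]
    if np.ptp(pg) <= cfg.amp_threshold:
        return "none"
    if traj is not None and not sustained_oscillation(
            traj, transient_ms=cfg.transient_ms, amp_threshold=cfg.amp_threshold):
        return "none"
    seg = w.p_sound[i0:]
    if _envelope_modulation(seg, w.fs_hz, cfg) > cfg.modulation_threshold:
        return "cry"
    freqs, power = _spectral_peaks(seg, w.fs_hz, cfg)
    if len(freqs) == 0:
        return "none"
    return "phee" if power[0] >= power.max() else "subharmonic_phee"


# ---------------------------------------------------------------------------
# landscapes and maps


@dataclass
class GainLandscape:
    """Gain and call-type label along the diagonal α = β = θ.

    theta : ascending grid in [0, 1.1].
    g : acoustic gain per θ (NaN where no call is produced).
    labels : call-type label per θ.
    half_T_us : one-way tract travel time used, μs.
    meta : provenance (γ, dt, duration, classifier settings).
    """

    theta: np.ndarray
    g: np.ndarray
    labels: np.ndarray
    half_T_us: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.theta) == len(self.g) == len(self.labels)):
            raise ValueError("landscape grids must be aligned")
        voiced = self.labels != "none"
        if np.any(~(self.g[voiced] > 0)):
            raise ValueError("labelled cells must carry positive gain")

    def region_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def to_csv(self, path) -> None:
        pd.DataFrame({"theta": self.theta, "g": self.g,
                      "label": self.labels}).to_csv(path, index=False)
        meta = dict(self.meta, half_T_us=self.half_T_us)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "GainLandscape":
        df = pd.read_csv(path)
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(df["theta"].to_numpy(), df["g"].to_numpy(),
                   df["label"].to_numpy(dtype=object),
                   meta.pop("half_T_us", float("nan")), meta)


def gain_landscape(
    theta_grid: np.ndarray | None = None,
    fold_gamma: float = 45.0,
    tract: TractParams | None = None,
    cfg: ClassifierConfig = ClassifierConfig(),
    duration_ms: float = 1000.0,
    init: FoldState = DEFAULT_INIT,
) -> GainLandscape:
    """Simulate, classify and measure gain at every θ of the diagonal grid.

    Each grid point is an independent constant-control simulation;
    points whose integration blows up or never sustains oscillation are
    labelled ``none`` with NaN gain.
    """
    theta = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    tract = tract if tract is not None else TractParams()
    g = np.full(len(theta), np.nan)
    labels = np.array(["none"] * len(theta), dtype=object)
    dt_ms = tract.dt * 1e-3
    for i, th in enumerate(theta):
        try:
            traj = simulate(None, FoldParams(th, th, fold_gamma), dt=dt_ms,
                            duration=duration_ms, init=init)
        except Exception:
            continue
        if not sustained_oscillation(traj, transient_ms=cfg.transient_ms,
                                     amp_threshold=cfg.amp_threshold):
            continue
        w = filter_glottal(traj.x, tract)
        lab = classify_call(w, cfg, traj=traj)
        labels[i] = lab
        if lab != "none":
            g[i] = gain(w, transient_ms=cfg.transient_ms)
    meta = {"gamma": fold_gamma, "dt_us": tract.dt,
            "duration_ms": duration_ms, "n_theta": len(theta),
            "classifier": asdict(cfg)}
    return GainLandscape(theta, g, labels, tract.half_T, meta)


@dataclass
class FrequencyAmplitudeMaps:
    """Per-cell glottal fundamental (kHz) and amplitude over an (α, β) grid.

    ``oscillating`` flags cells inside the calling regime; frequency and
    amplitude are NaN elsewhere.
    """

    alpha: np.ndarray
    beta: np.ndarray
    frequency_khz: np.ndarray
    amplitude: np.ndarray
    oscillating: np.ndarray


def glottal_fundamental_khz(traj: Trajectory, transient_ms: float = 100.0) -> float:
    """Dominant frequency of the post-transient fold displacement, kHz."""
    x = traj.x[traj.times >= transient_ms]
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
    freqs_hz = np.fft.rfftfreq(len(x), traj.dt * 1e-3)  # dt ms → seconds
    return float(freqs_hz[np.argmax(spec)] * 1e-3)


def frequency_amplitude_maps(
    alpha_grid: np.ndarray,
    beta_grid: np.ndarray,
    fold_gamma: float = 45.0,
    duration_ms: float = 500.0,
    dt_ms: float = 0.005,
    transient_ms: float = 100.0,
) -> FrequencyAmplitudeMaps:
    """Iso-frequency / iso-amplitude maps of the glottal flow.

    The fundamental is the dominant peak of the post-transient
    displacement spectrum and the amplitude its post-transient peak
    magnitude; non-oscillating cells are flagged.
    """
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, float))
    beta_grid = np.atleast_1d(np.asarray(beta_grid, float))
    shape = (len(beta_grid), len(alpha_grid))
    freq = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    osc = np.zeros(shape, dtype=bool)
    for j, b in enumerate(beta_grid):
        for i, a in enumerate(alpha_grid):
            try:
                traj = simulate(None, FoldParams(a, b, fold_gamma),
                                duration=duration_ms, dt=dt_ms)
            except Exception:
                continue
            if not sustained_oscillation(traj, transient_ms=transient_ms):
                continue
            osc[j, i] = True
            freq[j, i] = glottal_fundamental_khz(traj, transient_ms)
            xpost = traj.x[traj.times >= transient_ms]
            amp[j, i] = float(np.max(np.abs(xpost - xpost.mean())))
    return FrequencyAmplitudeMaps(alpha_grid, beta_grid, freq, amp, osc)
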