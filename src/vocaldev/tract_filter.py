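"""Source-filter stage: from fold displacement to emitted sound.

The glottal pressure is proportional to the fold displacement,
``P_glottal(t) = c · x(t)``.  The upper vocal tract is a uniform
cylinder of length ``L`` traversed one way in ``T/2 = L / c_sound``;
the supraglottal pressure follows the reflection recursion

    P_in(t) = c · x(t) − r · P_in(t − T/2),

with reflection coefficient ``r`` at the mouth, and the emitted sound is
the transmitted part, ``P_sound(t) = (1 − r) · P_in(t − T/2)``.  The
recursion's frequency response peaks where the delayed reflection
arrives in antiphase, i.e. at odd multiples of the closed-closed tube
fundamental ``f0 = c_sound / 2L = 1/T``; glottal flow oscillating at
``f0`` (or with harmonics falling on it) is therefore amplified, which
is the acoustic origin of the gain landscape.

Delays are handled in whole samples: the one-way travel time must be an
integer multiple of the sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vocaldev._kernels import tract_recursion

__all__ = [
    "TractParams",
    "SoundWaveforms",
    "SilentInputError",
    "filter_glottal",
    "gain",
    "resonance_frequency",
    "tract_length_from_f0",
    "frequency_response",
    "measured_resonance_khz",
]


class SilentInputError(ValueError):
    """Gain is undefined for a silent glottal input."""


@dataclass(frozen=True)
class TractParams:
    """Vocal-tract filter parameters.

    r : pressure reflection coefficient at the mouth, in [0, 1].
    c : linear pressure coefficient (glottal source strength).
    half_T : one-way sound travel time through the tract, μs.
    dt : sampling step, μs; ``half_T`` must be an integer multiple.
    c_sound : speed of sound, m/s.
    c3 : optional cubic source term of the third-order tract
        approximation; 0 disables it (first-order model).
    """

    r: float = 0.8
    c: float = 1.0
    half_T: float = 50.0
    dt: float = 5.0
    c_sound: float = 350.0
    c3: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("reflection coefficient r must be in [0, 1]")
        if self.c < 0:
            raise ValueError("pressure coefficient c must be non-negative")
        if not self.half_T > 0:
            raise ValueError("one-way travel time must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        n = self.half_T / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"one-way delay half_T={self.half_T} μs is not a whole number "
                f"of samples at dt={self.dt} μs; adjust dt so half_T/dt is an "
                "integer")

    @property
    def n_delay(self) -> int:
        """One-way delay in samples."""
        return int(round(self.half_T / self.dt))

    @property
    def length_mm(self) -> float:
        """Tract length from L = c_sound · T/2 (μs · m/s → mm)."""
        return self.c_sound * self.half_T * 1e-3

    @classmethod
    def from_length(cls, length_mm: float, dt: float = 5.0, **kw) -> "TractParams":
        """Build from a tract length, snapping dt so the delay is integral.

        The one-way time ``L / c_sound`` is generally not a multiple of
        the requested ``dt``; the step is refined to an integer divisor
        of the travel time no larger than ``dt``.
        """
        c_sound = kw.pop("c_sound", 350.0)
        half_T = length_mm / c_sound * 1e3  # mm / (m/s) → μs · 1e3
        n = max(1, int(np.ceil(half_T / dt)))
        return cls(half_T=half_T, dt=half_T / n, c_sound=c_sound, **kw)


@dataclass
class SoundWaveforms:
    """Glottal, supraglottal and emitted pressure series (equal length).

    ``p_sound`` is ``(1 − r) · p_in`` delayed by the one-way travel
    time, with a zero-padded head.  ``dt`` in μs.
    """

    p_glottal: np.ndarray
    p_in: np.ndarray
    p_sound: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.p_glottal) == len(self.p_in) == len(self.p_sound)):
            raise ValueError("waveform arrays must have equal length")

    @property
    def fs_hz(self) -> float:
        return 1e6 / self.dt

    @property
    def duration_ms(self) -> float:
        return len(self.p_sound) * self.dt * 1e-3


def filter_glottal(x_series: np.ndarray, tract: TractParams) -> SoundWaveforms:
    """Run the tract reflection recursion on a fold-displacement series.

    The recursion is seeded with the pure source term for the first
    ``n_delay`` samples (empty delay line), matching an index-shift
    implementation with zero initialisation.
    """
    x = np.ascontiguousarray(x_series, dtype=float)
    nd = tract.n_delay
    p_glottal = tract.c * x
    p_in = tract_recursion(x, tract.c, tract.c3, tract.r, nd)
    p_sound = np.zeros_like(p_in)
    if nd < len(p_in):
        p_sound[nd:] = (1.0 - tract.r) * p_in[:-nd]
    return SoundWaveforms(p_glottal, p_in, p_sound, tract.dt)


def gain(w: SoundWaveforms, transient_ms: float = 100.0) -> float:
    """Acoustic gain ``g = max|P_sound| / max|P_glottal|`` post-transient."""
    i0 = int(round(transient_ms * 1e3 / w.dt))
    if i0 >= len(w.p_glottal):
        raise ValueError("transient window longer than the waveform")
    g_max = np.max(np.abs(w.p_glottal[i0:]))
    if g_max <= 0.0:
        raise SilentInputError("glottal input is silent; gain undefined")
    return float(np.max(np.abs(w.p_sound[i0:])) / g_max)


def resonance_frequency(tract: TractParams) -> float:
    """Closed-closed tube fundamental ``f0 = 1/T = c_sound / 2L``, in kHz."""
    round_trip_us = 2.0 * tract.half_T
    return 1e3 / round_trip_us


def tract_length_from_f0(f0_khz: float, c_sound: float = 350.0) -> float:
    """Tract length (mm) from the resonance frequency: ``L = c_sound / 2 f0``.

    Exact inverse of :func:`resonance_frequency`.
    """
    if not f0_khz > 0:
        raise ValueError("resonance frequency must be positive")
    return c_sound / (2.0 * f0_khz)


def frequency_response(tract: TractParams, freq_khz) -> np.ndarray:
    """Analytic steady-state |P_sound/P_glottal| of the recursion.

    ``|H(f)| = (1 − r) / |1 + r e^{−i 2π f τ}|`` with τ the one-way
    delay; maxima at odd multiples of f0 = 1/(2τ).
    """
    f = np.asarray(freq_khz, dtype=float) * 1e3  # Hz
    tau = tract.half_T * 1e-6  # s
    den = np.abs(1.0 + tract.r * np.exp(-2j * np.pi * f * tau))
    return (1.0 - tract.r) / den


def measured_resonance_khz(tract: TractParams, n_fft: int = 1 << 16) -> float:
    """Resonance frequency measured from the filter's impulse response.

    Runs a unit impulse through the reflection recursion and returns the
    frequency of peak magnitude response (kHz).  This is the simulated
    counterpart of :func:`resonance_frequency` and agrees with it to
    within one FFT bin.
    """
    x = np.zeros(n_fft)
    x[0] = 1.0
    w = filter_glottal(x, tract)
    spec = np.abs(np.fft.rfft(w.p_sound))
    freqs = np.fft.rfftfreq(n_fft, tract.dt * 1e-6)  # Hz
    # all odd multiples of f0 share the same peak height; report the
    # fundamental, i.e. the lowest local maximum comparable to the global one
    interior = (spec[1:-1] >= spec[:-2]) & (spec[1:-1] >= spec[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[spec[idx] >= 0.5 * spec.max()]
    i_peak = idx[0] if len(idx) else int(np.argmax(spec))
    return float(freqs[i_peak] * 1e-3)
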