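"""Measurement pipeline for session audio.

Syllables are detected from the amplitude envelope of the 6-10 kHz
band (the band containing marmoset contact-call energy): the recording
is bandpass filtered, the magnitude of its analytic signal is taken as
the envelope, the envelope is decimated to 1 kHz and smoothed with a
50 Hz lowpass, and contiguous stretches above a threshold — the 99th
percentile of the envelope over a known-silent baseline segment —
become syllables.  Dominant frequency is the per-frame argmax-power
frequency of the spectrogram averaged over frames.  Same-type syllables
separated by less than 500 ms are grouped into multisyllabic calls, and
parental responses beginning within 5 s of an infant call's offset with
no intervening call are scored as contingent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Syllable",
    "CallEvent",
    "DetectionConfig",
    "detect_syllables",
    "dominant_frequency",
    "group_calls",
    "contingency_score",
]


@dataclass
class Syllable:
    """One detected syllable.  Times in seconds; frequency in kHz."""

    onset: float
    offset: float
    call_type: str | None = None
    dominant_frequency: float = float("nan")

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("syllable offset must exceed onset")


@dataclass
class CallEvent:
    """A (possibly multisyllabic) whole call."""

    onset: float
    offset: float
    call_type: str
    n_syllables: int = 1


@dataclass(frozen=True)
class DetectionConfig:
    """Detector settings.

    band_khz : detection passband (default 6-10 kHz).
    envelope_fs : rate to which the envelope is decimated, Hz.
    envelope_lowpass_hz : smoothing cutoff applied to the envelope.
    threshold_percentile : percentile of the baseline envelope used as
        the detection threshold.
    min_duration_s : syllables shorter than this are discarded
        (click suppression standing in for the study's human check).
    """

    band_khz: tuple = (6.0, 10.0)
    envelope_fs: float = 1000.0
    envelope_lowpass_hz: float = 50.0
    threshold_percentile: float = 99.0
    min_duration_s: float = 0.02


def _envelope_1khz(audio: np.ndarray, fs: float, cfg: DetectionConfig):
    lo, hi = (f * 1e3 for f in cfg.band_khz)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, audio)
    env = np.abs(sps.hilbert(band))
    dec = int(round(fs / cfg.envelope_fs))
    env = sps.resample_poly(env, 1, dec)
    fs_env = fs / dec
    sos_lp = sps.butter(4, cfg.envelope_lowpass_hz, fs=fs_env, output="sos")
    return np.maximum(sps.sosfiltfilt(sos_lp, env), 0.0), fs_env


def detect_syllables(
    audio: np.ndarray,
    fs: float,
    baseline: tuple,
    cfg: DetectionConfig = DetectionConfig(),
) -> list[Syllable]:
    """Detect syllable onsets/offsets from a recording.

    ``baseline`` is a ``(start_s, end_s)`` segment known to contain no
    calls; its 99th-percentile envelope value is the detection
    threshold.  Detections overlapping the baseline segment trigger a
    warning (the baseline was probably not silent).
    """
    audio = np.asarray(audio, dtype=float)
    if len(audio) == 0:
        return []
    if fs < 24_000:
        raise ValueError("sampling rate must be at least 24 kHz")
    b0, b1 = baseline
    if not (0 <= b0 < b1 <= len(audio) / fs):
        raise ValueError("baseline segment outside the recording")
    env, fs_env = _envelope_1khz(audio, fs, cfg)
    t = np.arange(len(env)) / fs_env
    base = env[(t >= b0) & (t < b1)]
    if len(base) == 0:
        raise ValueError("baseline segment too short")
    thresh = np.percentile(base, cfg.threshold_percentile)
    above = env > thresh
    edges = np.diff(above.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above[0]:
        onsets = np.insert(onsets, 0, 0)
    if above[-1]:
        offsets = np.append(offsets, len(above))
    sylls = []
    for i, j in zip(onsets, offsets):
        on, off = i / fs_env, j / fs_env
        if off - on < cfg.min_duration_s:
            continue
        if on < b1 and off > b0:
            warnings.warn("detection overlaps the baseline segment; "
                          "baseline may not be silent", RuntimeWarning,
                          stacklevel=2)
        sylls.append(Syllable(on, off))
    return sylls


def dominant_frequency(
    x: np.ndarray,
    fs: float,
    nperseg: int = 1024,
    overlap: float = 0.5,
) -> float:
    """Dominant frequency of a syllable, kHz.

    Average over spectrogram frames of the frequency at maximum power
    (1024-sample Hann windows, 50% overlap by default).
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("dominant frequency undefined for silent input")
    nperseg = min(nperseg, len(x))
    noverlap = int(nperseg * overlap)
    freqs, _, S = sps.spectrogram(x, fs=fs, window="hann", nperseg=nperseg,
                                  noverlap=noverlap)
    if S.shape[1] < 2:
        raise ValueError("syllable shorter than two spectrogram frames")
    peak_f = freqs[np.argmax(S, axis=0)]
    return float(np.mean(peak_f) * 1e-3)


def group_calls(syllables: list[Syllable], max_gap: float = 0.5) -> list[CallEvent]:
    """Greedy left-to-right grouping of typed syllables into whole calls.

    Consecutive same-type syllables with an inter-syllable gap strictly
    below ``max_gap`` merge; a type change always breaks the call.  The
    output intervals are disjoint and cover exactly the input syllables.
    """
    if not syllables:
        return []
    for s in syllables:
        if s.call_type is None:
            raise ValueError("syllables must be typed before grouping")
    order = sorted(syllables, key=lambda s: s.onset)
    for a, b in zip(order, order[1:]):
        if b.onset < a.offset:
            raise ValueError("overlapping syllables: malformed input")
    calls: list[CallEvent] = []
    cur = [order[0]]
    for s in order[1:]:
        gap = s.onset - cur[-1].offset
        if s.call_type == cur[-1].call_type and gap < max_gap:
            cur.append(s)
        else:
            calls.append(CallEvent(cur[0].onset, cur[-1].offset,
                                   cur[0].call_type, len(cur)))
            cur = [s]
    calls.append(CallEvent(cur[0].onset, cur[-1].offset,
                           cur[0].call_type, len(cur)))
    return calls


def contingency_score(
    infant_calls: list[CallEvent],
    parent_onsets: np.ndarray,
    window_s: float = 5.0,
    call_type: str = "phee",
) -> float:
    """Proportion F of infant calls receiving a contingent parental response.

    A parental call is contingent on an infant call when its onset
    follows the infant call's offset by less than ``window_s`` with no
    other call (infant or parent) in between.  F = contingent responses
    / infant calls of ``call_type``; callers restrict the lists to the
    period of interest (e.g. before the zero-crossing day).
    """
    targets = sorted((c for c in infant_calls if c.call_type == call_type),
                     key=lambda c: c.onset)
    if not targets:
        raise ValueError(f"no infant {call_type} calls: F undefined")
    parent_onsets = np.sort(np.asarray(parent_onsets, dtype=float))
    infant_onsets = np.sort(np.array([c.onset for c in infant_calls]))
    n_contingent = 0
    for c in targets:
        after = parent_onsets[(parent_onsets > c.offset)
                              & (parent_onsets < c.offset + window_s)]
        if len(after) == 0:
            continue
        first = after[0]
        # any other call starting strictly between offset and the response?
        other_infant = np.any((infant_onsets > c.offset)
                              & (infant_onsets < first))
        if not other_infant:
            n_contingent += 1
    return n_contingent / len(targets)
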