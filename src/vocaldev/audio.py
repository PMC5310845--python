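"""Small audio utilities: pink noise, resampling, PCM WAV I/O."""

from __future__ import annotations

import numpy as np
from fractions import Fraction

from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["pink_noise", "resample", "write_wav", "read_wav", "mix_at_snr"]


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pink (1/f-power) noise of length ``n``, normalised to unit RMS.

    Generated by shaping white Gaussian noise in the frequency domain
    with a 1/sqrt(f) amplitude envelope.
    """
    if n <= 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling between (rational-ratio) sample rates."""
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return resample_poly(x, frac.numerator, frac.denominator)


def mix_at_snr(signal: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Add ``noise`` scaled so the signal-to-noise RMS ratio is ``snr_db``."""
    ps = np.mean(signal**2)
    pn = np.mean(noise**2)
    if pn == 0 or ps == 0:
        return signal + noise
    k = np.sqrt(ps / (pn * 10.0 ** (snr_db / 10.0)))
    return signal + k * noise


def write_wav(path, x: np.ndarray, fs: int) -> None:
    """Write a float series as 16-bit PCM, peak-normalised to -1 dBFS."""
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * (10 ** (-1 / 20))
    wavfile.write(path, int(fs), np.round(x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV as float64 in [-1, 1] plus its sample rate."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(fs)
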