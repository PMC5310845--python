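"""Numba kernels for the sequential recursions.

The vocal-fold Euler recursion, the tract reflection recursion, and the
Langevin walk are inherently sequential, so they are compiled with numba
rather than vectorised.  The arithmetic order inside ``euler_fold``
reproduces the reference forward-Euler update term for term so that
trajectories are bit-reproducible against a plain-Python transcription.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: |x| beyond which the Euler integration is considered to have blown up
#: (step size too large for the stiffness of the oscillator).
BLOWUP_LIMIT = 1e3


@njit(cache=True)
def euler_fold(alpha, beta, gamma, dt, n_steps, x0, y0):  # pragma: no cover
    """Forward-Euler integration of the vocal-fold normal form.

    ``alpha`` and ``beta`` are per-step control values (length
    ``n_steps``).  Returns ``(x, y, n_valid)`` where ``n_valid`` is the
    number of valid samples (``n_steps + 1`` if no blow-up occurred).
    """
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    x[0] = x0
    y[0] = y0
    for n in range(n_steps):
        a = alpha[n]
        b = beta[n]
        x[n + 1] = x[n] + dt * y[n]
        y[n + 1] = y[n] + dt * (
            -a * gamma**2
            - b * gamma**2 * x[n]
            + gamma**2 * x[n] ** 2
            - gamma * x[n] * y[n]
            - gamma**2 * x[n] ** 3
            - gamma * x[n] ** 2 * y[n]
        )
        if not (abs(x[n + 1]) <= BLOWUP_LIMIT):
            return x, y, n + 2
    return x, y, n_steps + 1


@njit(cache=True)
def tract_recursion(x, c, c3, r, n_delay):  # pragma: no cover
    """Supraglottal pressure by the reflection recursion.

    ``p[i] = c*x[i] + c3*x[i]**3 - r*p[i - n_delay]``, with the pure
    source term for the first ``n_delay`` samples (the delay line is
    initialised empty).  ``c3`` is the optional cubic source term of the
    third-order tract approximation; it is zero in the first-order model.
    """
    p = np.empty_like(x)
    for i in range(x.shape[0]):
        src = c * x[i] + c3 * x[i] ** 3
        if i < n_delay:
            p[i] = src
        else:
            p[i] = src - r * p[i - n_delay]
    return p


@njit(cache=True)
def langevin_walk(theta0, grad, grid, lo, hi, drift_dt, noise_scale,
                  n_steps, record_every, seed):  # pragma: no cover
    """Reflected overdamped Langevin walk on a 1-D cost landscape.

    ``grad`` holds dC/dθ sampled on ``grid``; the walk linearly
    interpolates it.  Positions are recorded every ``record_every``
    steps (plus the start).  Returns the recorded positions, the final
    position, and the number of proposed moves that left the domain
    before reflection (used by the step-size guard).
    """
    np.random.seed(seed)
    n_rec = n_steps // record_every
    out = np.empty(n_rec + 1)
    out[0] = theta0
    th = theta0
    n_out = 0
    width = hi - lo
    for i in range(n_steps):
        drift = np.interp(th, grid, grad)
        th = th - drift * drift_dt + noise_scale * np.random.standard_normal()
        if th < lo or th > hi:
            n_out += 1
            # reflect into [lo, hi] (possibly repeatedly)
            for _ in range(100):
                if th < lo:
                    th = 2.0 * lo - th
                elif th > hi:
                    th = 2.0 * hi - th
                else:
                    break
            if th < lo or th > hi:
                th = lo + 0.5 * width
        if (i + 1) % record_every == 0:
            out[(i + 1) // record_every] = th
    return out, th, n_out
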