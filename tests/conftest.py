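"""Shared fixtures: expensive gain landscapes are built once per session."""

import numpy as np
import pytest

from vocaldev import call_catalog as cc
from vocaldev import synthetic_data as sd
from vocaldev.tract_filter import TractParams


@pytest.fixture(scope="session")
def gl_full():
    """Full-resolution gain landscape at the reference tract parameters
    (γ=45/ms, c=1, r=0.8, T/2=50 μs, dt=5 μs; 221 θ points, 1-s calls)."""
    return cc.gain_landscape()


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort configuration used by unit tests: 3 infants, a
    coarser θ grid and shorter calls keep simulation cost low while
    preserving the landscape structure."""
    return sd.CohortConfig(n_infants=3, theta_n=111, call_duration_ms=400.0)


@pytest.fixture(scope="session")
def small_cache(small_cfg):
    return sd.landscape_cache(small_cfg)


@pytest.fixture(scope="session")
def gl_small(small_cache):
    """Coarse-grid landscape at the reference tract delay (T/2 = 50 μs)."""
    return small_cache[50.0]


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_cache):
    from vocaldev.synthetic_data import SyntheticCohort, generate_infant
    import pandas as pd

    ss = np.random.SeedSequence(2024)
    frames, truth = [], {}
    for i, child in enumerate(ss.spawn(small_cfg.n_infants)):
        seed = int(child.generate_state(1)[0] % (2**31))
        s, t = generate_infant(small_cfg, seed, f"inf{i}", small_cache)
        frames.append(s)
        truth[f"inf{i}"] = t
    return SyntheticCohort(pd.concat(frames, ignore_index=True), truth,
                           small_cfg, 2024)


@pytest.fixture(scope="session")
def reference_tract():
    return TractParams()
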