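"""Shared fixtures: small synthetic sessions and derived source estimates."""

from __future__ import annotations

import math

import numpy as np
import pytest

from munet.inverse import eloreta_filter, project_sources, reduce_orientation
from munet.synthgen import (CouplingTarget, SimConfig, simulate_session,
                            LM1_MNI, LSMA_MNI, RM1_MNI)


@pytest.fixture(scope="session")
def small_session():
    """Default-grid session with 60 trials (64 sensors, 50 sources)."""
    return simulate_session(SimConfig(n_trials=60, seed=2), return_sources=True)


@pytest.fixture(scope="session")
def small_sources(small_session):
    """eLORETA source estimates of the small session."""
    red = reduce_orientation(small_session.leadfield)
    filt = eloreta_filter(red)
    return project_sources(filt, small_session.eeg), filt


def make_patch_grid(rng: np.random.Generator, patch_size: int = 5,
                    n_background: int = 20, min_sep: float = 25.0):
    """Seed + two coupled voxel patches (lSMA, rM1) + distant background."""

    def patch(center):
        return np.array([center] + [center + rng.normal(0, 5.0, 3)
                                    for _ in range(patch_size - 1)])

    parts = [LM1_MNI[None, :], patch(LSMA_MNI), patch(RM1_MNI)]
    bg: list[np.ndarray] = []
    while len(bg) < n_background:
        p = rng.uniform(-70, 70, 3)
        if np.linalg.norm(p) > 70:
            continue
        allp = np.vstack(parts + ([np.array(bg)] if bg else []))
        if np.min(np.linalg.norm(allp - p, axis=1)) < min_sep:
            continue
        bg.append(p)
    return np.vstack(parts + [np.array(bg)]), patch_size


@pytest.fixture(scope="session")
def patch_session():
    """Session with 5-voxel coupled patches at the lSMA and rM1 centroids."""
    rng = np.random.default_rng(11)
    pos, ps = make_patch_grid(rng)
    targets = (
        [CouplingTarget(i, phase_offset=math.pi / 2, kappa_mean=0.7,
                        kappa_spread=0.2, delay_ms=-10.0, name=f"sma{i}")
         for i in range(1, 1 + ps)]
        + [CouplingTarget(i, phase_offset=-math.pi / 2, kappa_mean=0.6,
                          kappa_spread=0.2, name=f"rm1{i}")
           for i in range(1 + ps, 1 + 2 * ps)]
    )
    cfg = SimConfig(n_trials=120, source_positions=pos,
                    coupling_targets=targets, seed=3)
    ses = simulate_session(cfg, return_sources=True)
    red = reduce_orientation(ses.leadfield)
    filt = eloreta_filter(red)
    sources = project_sources(filt, ses.eeg)
    return ses, sources, ps
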