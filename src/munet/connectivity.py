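"""Narrowband analytic signals, imaginary phase-locking value (iPLV) maps and cROIs.

The iPLV between a seed phase series φ_S(t) and a target series φ_T(t) is

    iPLV = | Im( ⟨ exp(i·(φ_S − φ_T)) ⟩ ) |

with the expectation taken over time within a trial (per-trial values) and
results averaged across trials for subject-level seed maps.  Taking only the
imaginary part discards zero-lag coupling, making the measure insensitive to
instantaneous volume-conduction mixing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

__all__ = [
    "AnalyticEpoch", "ConnectivityMap", "CRoi", "narrowband_analytic",
    "iplv_trial", "seed_map", "group_map", "extract_crois", "croi_trial_values",
]


@dataclass
class AnalyticEpoch:
    """Complex analytic representation of a narrowband signal."""

    analytic: np.ndarray          # complex, same shape as input
    f_c: float
    bandwidth: float
    fs: float
    ar_fallback: bool = False     # True if AR padding fell back to reflection

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.analytic)

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.analytic)


@dataclass
class ConnectivityMap:
    """Seed-based iPLV per source. The seed's own entry is defined as 0."""

    values: np.ndarray
    positions: np.ndarray
    seed_index: int
    seed_position: np.ndarray
    frequency: float
    level: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.values) != len(self.positions):
            raise ValueError("values and positions must align")


@dataclass
class CRoi:
    """Connectivity region of interest: a cluster of seed-coupled sources."""

    name: str
    members: np.ndarray
    centroid: np.ndarray
    mean_iplv: float

    def to_dict(self) -> dict:
        return {"name": self.name, "members": [int(m) for m in self.members],
                "centroid": [float(c) for c in self.centroid],
                "mean_iplv": float(self.mean_iplv)}


# --------------------------------------------------------------------------- #
# analytic signal
# --------------------------------------------------------------------------- #

def _yule_walker(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by Yule-Walker with biased autocovariance (stable)."""
    x = x - x.mean()
    n = len(x)
    acov = np.array([np.dot(x[: n - k], x[k:]) for k in range(order + 1)]) / n
    if acov[0] <= 0:
        raise np.linalg.LinAlgError("zero-variance signal")
    from scipy.linalg import solve_toeplitz
    return solve_toeplitz(acov[:order], acov[1: order + 1])


def _ar_fit_ls(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by least squares on the prediction equations."""
    x = x - x.mean()
    n = len(x)
    X = np.column_stack([x[order - 1 - k: n - 1 - k] for k in range(order)])
    rho, *_ = np.linalg.lstsq(X, x[order:], rcond=None)
    return rho


def _ar_extend(x: np.ndarray, order: int, n_pad: int,
               method: str = "ls") -> tuple[np.ndarray, bool]:
    """Pad both ends of ``x`` with AR(order) forecasts; returns (padded, fallback)."""
    try:
        if np.allclose(x, x[0]):
            raise np.linalg.LinAlgError("constant signal")
        rho = _ar_fit_ls(x, order) if method == "ls" else _yule_walker(x, order)
        mu = x.mean()
        xc = x - mu
        a = np.r_[1.0, -rho]

        def forecast(series: np.ndarray) -> np.ndarray:
            # free-run the AR recursion from the last `order` samples
            zi = signal.lfiltic([1.0], a, series[::-1][:order])
            return signal.lfilter([1.0], a, np.zeros(n_pad), zi=zi)[0]

        fwd = forecast(xc) + mu
        bwd = (forecast(xc[::-1]) + mu)[::-1]
        padded = np.concatenate([bwd, x, fwd])
        lim = 1e3 * (np.sqrt(np.mean(xc ** 2)) + 1e-30)
        if not np.all(np.isfinite(padded)) or \
                max(np.abs(fwd).max(), np.abs(bwd).max()) > lim:
            raise np.linalg.LinAlgError("explosive AR forecast")
        return padded, False
    except np.linalg.LinAlgError:
        pad = min(n_pad, len(x) - 1)
        left = x[1: pad + 1][::-1]
        right = x[-pad - 1: -1][::-1]
        padded = np.concatenate([left, x, right])
        if pad < n_pad:  # re-pad edges if the signal was very short
            padded = np.pad(padded, n_pad - pad, mode="edge")
        return padded, True


def narrowband_analytic(x: np.ndarray, f_c: float, fs: float,
                        bw: float = 2.0, pad_ms: float = 64.0,
                        ar_order: int = 30,
                        guard_ms: float = 1536.0) -> AnalyticEpoch:
    """AR-pad, band-pass and Hilbert-transform signals along the last axis.

    Each epoch is extended at both ends with forecasts from an
    AR(``ar_order``) model fitted per epoch (least-squares fit, reflection
    fallback for degenerate signals), then band-passed f_c ± bw/2 with a
    two-pass (zero-phase) fourth-order Butterworth filter and Hilbert
    transformed; the padding is trimmed afterwards.  The forecast runs for
    ``pad_ms + guard_ms``: the guard interval exists because the impulse
    response of a 2 Hz-wide two-pass Butterworth band-pass decays over more
    than a second, so a 64 ms pad alone cannot keep the filter transient out
    of the retained window.
    """
    x = np.asarray(x, dtype=float)
    if f_c - bw / 2 <= 0:
        raise ValueError("band must lie above 0 Hz")
    n_t = x.shape[-1]
    if n_t < 4 * ar_order:
        raise ValueError("epoch too short for the AR padding order")
    sos = signal.butter(4, [f_c - bw / 2, f_c + bw / 2], btype="bandpass",
                        fs=fs, output="sos")
    n_pad = int(round((pad_ms + guard_ms) * fs / 1000.0))

    flat = x.reshape(-1, n_t)
    out = np.empty((flat.shape[0], n_t), dtype=complex)
    fallback = False
    for i, row in enumerate(flat):
        padded, fb = _ar_extend(row, ar_order, n_pad)
        fallback |= fb
        filt = signal.sosfiltfilt(sos, padded)
        out[i] = signal.hilbert(filt)[n_pad: n_pad + n_t]
    return AnalyticEpoch(out.reshape(x.shape), f_c, bw, fs, ar_fallback=fallback)


# --------------------------------------------------------------------------- #
# iPLV
# --------------------------------------------------------------------------- #

def iplv_trial(phase_seed: np.ndarray, phase_target: np.ndarray) -> float:
    """Within-trial iPLV between two phase series (radians).

    Returns |Im(mean(exp(i(φ_S − φ_T))))| ∈ [0, 1]; exactly 0 for any
    zero-lag (scaled) copy of the seed.
    """
    phase_seed = np.asarray(phase_seed, dtype=float)
    phase_target = np.asarray(phase_target, dtype=float)
    if phase_seed.shape != phase_target.shape or phase_seed.size < 2:
        raise ValueError("phase series must have equal length >= 2")
    if np.any(~np.isfinite(phase_seed)) or np.any(~np.isfinite(phase_target)):
        raise ValueError("phase series contain non-finite values")
    return float(abs(np.mean(np.exp(1j * (phase_seed - phase_target))).imag))


def _trial_iplv_matrix(phases: np.ndarray, seed_index: int) -> np.ndarray:
    """Per-trial iPLV of every source to the seed. phases: (n_src, n_t, n_trials)."""
    dphi = phases[seed_index][None, :, :] - phases
    return np.abs(np.mean(np.exp(1j * dphi), axis=1).imag)   # (n_src, n_trials)


def seed_map(sources: np.ndarray, seed_index: int, f_mu: float, fs: float,
             positions: np.ndarray, bw: float = 2.0, pad: str = "ar",
             trial_average: str = "per_trial") -> tuple[ConnectivityMap, np.ndarray]:
    """Subject-level seed-based iPLV map plus the per-trial values per target.

    Parameters
    ----------
    sources : ndarray (n_sources, n_times, n_trials)
        Source-space time-courses of the pre-pulse window.
    trial_average : {'per_trial', 'coherent'}
        'per_trial' (default): map value = across-trial mean of per-trial
        iPLVs.  'coherent': |Im| of the phasor mean taken jointly across
        time and trials.
    pad : {'ar', 'reflect'}
        Padding mode for the analytic transform ('reflect' is faster for
        large grids).
    """
    sources = np.asarray(sources, dtype=float)
    n_src, n_t, n_trials = sources.shape
    if not 0 <= seed_index < n_src:
        raise ValueError("invalid seed index")
    if n_trials < 20:
        raise ValueError("need at least 20 trials for a stable map")
    if pad == "ar":
        ana = narrowband_analytic(np.moveaxis(sources, 1, -1), f_mu, fs, bw=bw)
        phases = np.moveaxis(ana.phase, -1, 1)
    else:
        sos = signal.butter(4, [f_mu - bw / 2, f_mu + bw / 2],
                            btype="bandpass", fs=fs, output="sos")
        n_pad = int(round((64 + 1536) * fs / 1000.0))
        padded = np.pad(sources, ((0, 0), (n_pad, n_pad), (0, 0)),
                        mode="reflect")
        filt = signal.sosfiltfilt(sos, padded, axis=1)
        phases = np.angle(signal.hilbert(filt, axis=1)[:, n_pad: n_pad + n_t])

    trial_vals = _trial_iplv_matrix(phases, seed_index)
    if trial_average == "coherent":
        dphi = phases[seed_index][None] - phases
        values = np.abs(np.mean(np.exp(1j * dphi), axis=(1, 2)).imag)
    else:
        values = trial_vals.mean(axis=1)
    values[seed_index] = 0.0
    cmap = ConnectivityMap(values=values, positions=positions,
                           seed_index=seed_index,
                           seed_position=positions[seed_index],
                           frequency=f_mu, level="subject")
    return cmap, trial_vals


def group_map(maps: list[ConnectivityMap]) -> ConnectivityMap:
    """Element-wise mean of subject maps defined on identical grids."""
    if not maps:
        raise ValueError("no maps given")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or \
                not np.allclose(m.positions, first.positions):
            raise ValueError("subject maps are not on the same source grid")
    values = np.mean([m.values for m in maps], axis=0)
    return ConnectivityMap(values=values, positions=first.positions,
                           seed_index=first.seed_index,
                           seed_position=first.seed_position,
                           frequency=float(np.mean([m.frequency for m in maps])),
                           level="group")


# --------------------------------------------------------------------------- #
# cROI extraction
# --------------------------------------------------------------------------- #

def extract_crois(group: ConnectivityMap, quantile: float = 0.95,
                  link_mm: float = 15.0, seed_exclusion_mm: float = 20.0,
                  min_size: int = 5) -> list[CRoi]:
    """Cluster supra-threshold sources of a group map into connectivity ROIs.

    Sources above the ``quantile`` of map values and farther than
    ``seed_exclusion_mm`` from the seed are clustered by single linkage at
    ``link_mm``; clusters of at least ``min_size`` sources are returned,
    sorted by mean iPLV (descending), with iPLV-weighted centroids.
    """
    vals = group.values
    if np.any(~np.isfinite(vals)):
        raise ValueError("group map contains non-finite values")
    thresh = np.quantile(vals, quantile)
    dist_seed = np.linalg.norm(group.positions - group.seed_position, axis=1)
    cand = np.flatnonzero((vals >= thresh) & (dist_seed > seed_exclusion_mm)
                          & (np.arange(len(vals)) != group.seed_index))
    if cand.size == 0:
        raise ValueError("no cROI: no suprathreshold sources outside the seed zone")
    pos = group.positions[cand]
    adj = cdist(pos, pos) <= link_mm
    n_comp, labels = connected_components(adj, directed=False)
    rois: list[CRoi] = []
    for c in range(n_comp):
        members = cand[labels == c]
        if len(members) < min_size:
            continue
        w = vals[members]
        centroid = (group.positions[members] * w[:, None]).sum(0) / w.sum()
        rois.append(CRoi(name="", members=members, centroid=centroid,
                         mean_iplv=float(w.mean())))
    if not rois:
        raise ValueError("no cROI: no cluster reaches the minimum size")
    rois.sort(key=lambda r: r.mean_iplv, reverse=True)
    for i, r in enumerate(rois):
        r.name = r.name or f"cROI{i + 1}"
    return rois


def croi_trial_values(sources: np.ndarray, seed_index: int, croi: CRoi,
                      f_mu: float, fs: float, bw: float = 2.0,
                      pad: str = "ar") -> np.ndarray:
    """Per-trial iPLV between the seed and a cROI's averaged time-course.

    Member voxel time-courses are sign-aligned (by the sign of their
    correlation with the first member, computed on trial-concatenated data)
    before averaging, so that anti-phase filter polarities do not cancel.
    """
    sources = np.asarray(sources, dtype=float)
    members = np.asarray(croi.members, dtype=int)
    ref = sources[members[0]].ravel()
    signs = np.array([math.copysign(1.0, float(np.dot(sources[m].ravel(), ref)))
                      for m in members])
    avg = np.tensordot(signs, sources[members], axes=(0, 0)) / len(members)
    pair = np.stack([sources[seed_index], avg])       # (2, n_t, n_trials)
    _, trial_vals = seed_map(pair, 0, f_mu, fs,
                             positions=np.zeros((2, 3)), bw=bw, pad=pad)
    return trial_vals[1]


def crois_to_json(rois: list[CRoi]) -> str:
    return json.dumps([r.to_dict() for r in rois], indent=2)
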