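"""Synthetic EEG-TMS session generator with known coupling, phase and MEP ground truth.

The generator emulates the ingredients of a brain-state-dependent TMS
experiment: μ-band (9-13 Hz) cortical oscillators at the left primary motor
cortex (lM1, the stimulation seed), the left supplementary motor area (lSMA)
and the right motor cortex (rM1), whose phases are entrained to the seed with
a per-trial coupling strength κ; 1/f background sources and sensor noise
mixed instantaneously through a smooth lead field; and a two-muscle EMG trace
per trial carrying a stimulus artifact and a biphasic motor-evoked potential
(MEP) whose log amplitude depends linearly on the per-trial couplings and on
the μ phase at the pulse:

    log A_k = β0 + β_SMA·κ_k(SMA) + β_M1·κ_k(rM1) + β_phase·cos(φ_k − φ*) + ε_k

Phase dynamics are an Ornstein-Uhlenbeck diffusion around the linear ramp
2π·f_μ·t; coupling is a per-trial convex mix of the target phase towards the
(optionally delayed) seed phase plus a constant offset, with weight κ_k drawn
from a Beta distribution.  This gives a controllable ground-truth mapping
from κ to the imaginary phase-locking value measured downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochedRecording, LeadField

# Canonical MNI coordinates (mm) of the motor-network nodes.
LM1_MNI = np.array([-45.9, -9.9, 54.6])
LSMA_MNI = np.array([-12.0, -11.0, 74.0])
RM1_MNI = np.array([40.0, -25.0, 52.0])


# --------------------------------------------------------------------------- #
# configuration dataclasses
# --------------------------------------------------------------------------- #

@dataclass
class CouplingTarget:
    """One source entrained to the seed oscillator.

    ``delay_ms`` shifts the seed phase the target locks to: negative values
    make the target *lead* the seed (e.g. SMA driving M1).
    """

    source_index: int
    phase_offset: float = math.pi / 2
    kappa_mean: float = 0.5
    kappa_spread: float = 0.2
    delay_ms: float = 0.0
    name: str = ""


@dataclass
class NoiseConfig:
    background_level: float = 1.0   # RMS of each 1/f background source, source units
    sensor_noise_sd: float = 0.5    # µV, white, independent per sensor
    emg_noise_sd: float = 0.010     # mV, white EMG baseline noise


@dataclass
class MEPModelConfig:
    """Linear model for log peak-to-peak MEP amplitude (amplitudes in mV)."""

    beta0: float = 0.0
    beta_sma: float = 0.5
    beta_m1: float = 0.3
    beta_phase: float = 0.2
    preferred_phase: float = 0.0
    noise_sd: float = 0.5
    muscle_noise_sd: float = 0.05   # extra per-muscle log jitter (FDI vs APB)


@dataclass
class ArtifactConfig:
    amplitude: float = 5.0   # mV at t = 0
    tau_ms: float = 5.0      # exponential decay constant


@dataclass
class SimConfig:
    """Full description of one synthetic session (one "subject")."""

    n_trials: int = 1000
    isi_s: float = 2.0            # inter-stimulus interval, bookkeeping only
    isi_jitter_s: float = 0.25
    fs_raw: float = 5000.0
    fs_out: float = 1000.0
    n_sensors: int = 64
    source_positions: np.ndarray | None = None
    f_mu: float = 11.0
    coupling_targets: list[CouplingTarget] = field(default_factory=list)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    mep_model: MEPModelConfig = field(default_factory=MEPModelConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    osc_amplitude: float = 1.0
    phase_sd: float = 1.2         # stationary SD of the OU phase deviation (rad)
    phase_tau_s: float = 0.12     # OU relaxation time (s)
    mep_latency_ms: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (9.0 <= self.f_mu <= 13.0):
            raise ValueError("f_mu must lie within the 9-13 Hz μ range")
        if self.fs_raw % self.fs_out:
            raise ValueError("fs_raw must be an integer multiple of fs_out")
        if self.source_positions is None:
            self.source_positions = default_source_grid()
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        if not np.all(np.isfinite(self.source_positions)):
            raise ValueError("source positions must be finite")
        if not self.coupling_targets:
            self.coupling_targets = [
                CouplingTarget(1, phase_offset=math.pi / 2, kappa_mean=0.5,
                               kappa_spread=0.2, delay_ms=-10.0, name="lSMA"),
                CouplingTarget(2, phase_offset=-math.pi / 2, kappa_mean=0.4,
                               kappa_spread=0.2, delay_ms=0.0, name="rM1"),
            ]
        for t in self.coupling_targets:
            if not (0.0 <= t.kappa_mean <= 1.0):
                raise ValueError("kappa_mean must lie in [0, 1]")


@dataclass
class SyntheticSession:
    """Generated session: epoched EEG (µV), EMG (mV), lead field and truth table."""

    eeg: EpochedRecording
    emg: EpochedRecording
    leadfield: LeadField
    truth: pd.DataFrame
    cfg: SimConfig
    sources: np.ndarray | None = None   # optional (n_sources, n_times, n_trials)

    def __post_init__(self) -> None:
        n = self.eeg.n_trials
        if self.emg.n_trials != n or len(self.truth) != n:
            raise ValueError("trial counts must match across eeg/emg/truth")
        ph = self.truth["phase_at_pulse"].to_numpy()
        if np.any(ph <= -math.pi) or np.any(ph > math.pi):
            raise ValueError("truth phases must lie in (-pi, pi]")


# --------------------------------------------------------------------------- #
# source grid and lead field
# --------------------------------------------------------------------------- #


@lru_cache(maxsize=8)
def _cached_source_grid(n_background: int, seed: int) -> np.ndarray:
    return _build_source_grid(n_background, seed)


def default_source_grid(n_background: int = 47, seed: int = 7) -> np.ndarray:
    """Cached copy of :func:`_build_source_grid` with the default layout."""
    return _cached_source_grid(n_background, seed).copy()


def _build_source_grid(n_background: int = 47, seed: int = 7) -> np.ndarray:
    """Motor-network nodes plus quasi-random background sources in the head.

    Index 0 is the lM1 seed, 1 is lSMA, 2 is rM1.  Background positions are
    drawn once from a fixed-seed generator inside a 70 mm radius sphere,
    rejecting points closer than 12 mm to any previous source.
    """
    rng = np.random.default_rng(seed)
    pts = [LM1_MNI.copy(), LSMA_MNI.copy(), RM1_MNI.copy()]
    while len(pts) < 3 + n_background:
        p = rng.uniform(-70, 70, 3)
        if np.linalg.norm(p) > 70:
            continue
        if min(np.linalg.norm(p - q) for q in pts) < 12:
            continue
        pts.append(p)
    return np.array(pts)


def _fibonacci_hemisphere(n: int, radius: float = 95.0) -> np.ndarray:
    """Quasi-uniform sensor positions on an upper hemisphere (z > 0)."""
    k = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = (k + 0.5) / n            # in (0, 1): upper hemisphere only
    phi = 2 * np.pi * k / golden
    r = np.sqrt(1 - z ** 2)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_lead_field(n_sensors: int, source_positions: np.ndarray,
                    seed: int = 0) -> LeadField:
    """Build a smooth free-orientation lead field on a hemispheric sensor array.

    The gain uses the infinite-homogeneous-medium current-dipole kernel
    g(s, p, e) = e·(s − p)/‖s − p‖³, which is linear in the dipole moment and
    decays with sensor-source distance.  Columns are globally rescaled so a
    unit-moment source produces sensor signals of order 1 µV.  Deterministic
    in ``seed`` (small seeded jitter applied to sensor positions).
    """
    if n_sensors < 8:
        raise ValueError("need at least 8 sensors")
    pos = np.asarray(source_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) < 2:
        raise ValueError("need at least 2 source positions of dimension 3")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if np.any(d < 1e-9):
        raise ValueError("duplicate source positions")

    rng = np.random.default_rng(seed)
    sensors = _fibonacci_hemisphere(n_sensors) + rng.normal(0, 2.0, (n_sensors, 3))

    diff = sensors[:, None, :] - pos[None, :, :]          # (n_sens, n_src, 3)
    r3 = np.linalg.norm(diff, axis=-1, keepdims=True) ** 3
    gain = diff / r3
    # scale so the median per-source column norm is ~1 (µV per unit moment)
    scale = np.median(np.linalg.norm(gain, axis=0))
    gain = gain / scale
    return LeadField(gain=gain, positions=pos, sensor_positions=sensors)


# --------------------------------------------------------------------------- #
# stochastic ingredients
# --------------------------------------------------------------------------- #

def _ou_deviation(rng: np.random.Generator, n_times: int, n_trials: int,
                  dt: float, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck process, shape (n_times, n_trials)."""
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1 - a * a)
    drive = rng.standard_normal((n_times, n_trials), dtype=np.float32)
    drive = drive.astype(float)
    drive[0] *= sd                                  # stationary start
    drive[1:] *= innov_sd
    # x[t] = a·x[t-1] + drive[t] as an IIR filter down the time axis
    return signal.lfilter([1.0], [1.0, -a], drive, axis=0)


def _draw_kappa(rng: np.random.Generator, mean: float, spread: float,
                n: int) -> np.ndarray:
    """Per-trial coupling strengths from a Beta distribution with given mean/SD."""
    if spread <= 0:
        return np.full(n, mean)
    if mean <= 0.0 or mean >= 1.0:
        return np.full(n, float(np.clip(mean, 0.0, 1.0)))
    max_var = mean * (1 - mean)
    var = min(spread ** 2, 0.95 * max_var)
    nu = max_var / var - 1.0
    return rng.beta(mean * nu, (1 - mean) * nu, n)


def _one_over_f(rng: np.random.Generator, shape: tuple[int, int, int],
                fs: float) -> np.ndarray:
    """1/f-spectrum noise along axis 1, unit RMS."""
    n_t = shape[1]
    white = rng.normal(0, 1, shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_t, 1 / fs)
    amp = np.ones_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp[None, :, None], n=n_t, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _phase_tracks(cfg: SimConfig, rng: np.random.Generator,
                  n_extra: int) -> tuple[np.ndarray, dict[int, np.ndarray],
                                         dict[int, np.ndarray]]:
    """Seed and target phase tracks on the epoch grid extended to t = 0.

    Returns ``(phi_seed, phi_targets, kappas)`` where the phase arrays are
    (n_times + n_extra, n_trials).
    """
    fs = cfg.fs_out
    dt = 1.0 / fs
    n_times = int(round(1000 * fs / 1000))  # 1000 samples covering -1004..-5 ms
    n_tot = n_times + n_extra
    t = np.arange(n_tot) * dt
    ramp = 2 * math.pi * cfg.f_mu * t

    def one_track() -> np.ndarray:
        psi0 = rng.uniform(-math.pi, math.pi, cfg.n_trials)
        dev = _ou_deviation(rng, n_tot, cfg.n_trials, dt, cfg.phase_sd,
                            cfg.phase_tau_s)
        return ramp[:, None] + psi0[None, :] + dev

    phi_seed = one_track()
    phi_targets: dict[int, np.ndarray] = {}
    kappas: dict[int, np.ndarray] = {}
    for tgt in cfg.coupling_targets:
        kappa = _draw_kappa(rng, tgt.kappa_mean, tgt.kappa_spread, cfg.n_trials)
        indep = one_track()
        dshift = int(round(tgt.delay_ms * fs / 1000.0))
        # seed phase the target locks to, shifted by the coupling delay
        if dshift == 0:
            ref = phi_seed
        else:
            ref = np.roll(phi_seed, dshift, axis=0)
            if dshift > 0:       # target lags: extrapolate the leading edge
                ref[:dshift] = phi_seed[:dshift] - 2 * math.pi * cfg.f_mu * dshift * dt
            else:
                ref[dshift:] = phi_seed[dshift:] - 2 * math.pi * cfg.f_mu * dshift * dt
        phi_targets[tgt.source_index] = (
            (1 - kappa)[None, :] * indep + kappa[None, :] * (ref + tgt.phase_offset)
        )
        kappas[tgt.source_index] = kappa
    return phi_seed, phi_targets, kappas


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return math.pi - np.mod(math.pi - phase, 2 * math.pi)


# --------------------------------------------------------------------------- #
# MEP waveform and injection
# --------------------------------------------------------------------------- #

def _mep_template(fs: float, width_ms: float = 5.0,
                  dur_ms: float = 30.0) -> np.ndarray:
    """Biphasic MEP waveform (difference of two Gaussians), unit peak-to-peak."""
    t = np.arange(int(round(dur_ms * fs / 1000.0))) / fs * 1000.0  # ms
    s = width_ms / 2.5
    w = (np.exp(-0.5 * ((t - dur_ms / 2 + width_ms / 2) / s) ** 2)
         - np.exp(-0.5 * ((t - dur_ms / 2 - width_ms / 2) / s) ** 2))
    return w / (w.max() - w.min())


def inject_mep(trace: np.ndarray, amplitude: float, latency_ms: float,
               artifact: ArtifactConfig, fs: float,
               pulse_index: int) -> np.ndarray:
    """Add a biphasic MEP and an exponential stimulus artifact to an EMG trace.

    ``trace`` is a 1-D EMG record (mV) with the TMS pulse at sample
    ``pulse_index``.  The MEP template is normalised so the injected
    peak-to-peak amplitude equals ``amplitude`` (mV); the artifact
    A·exp(−t/τ) is added from t = 0 onward.  Returns a new array.
    """
    if amplitude < 0:
        raise ValueError("MEP amplitude must be non-negative")
    trace = np.asarray(trace, dtype=float)
    if latency_ms <= 0 or pulse_index + latency_ms * fs / 1000.0 >= len(trace):
        raise ValueError("MEP latency must fall inside the post-pulse window")
    out = trace.copy()
    n_post = len(trace) - pulse_index
    t_post = np.arange(n_post) / fs * 1000.0
    out[pulse_index:] += artifact.amplitude * np.exp(-t_post / artifact.tau_ms)
    tpl = _mep_template(fs)
    i0 = pulse_index + int(round(latency_ms * fs / 1000.0)) - len(tpl) // 2
    i0 = max(i0, pulse_index)
    seg = slice(i0, min(i0 + len(tpl), len(out)))
    out[seg] += amplitude * tpl[: seg.stop - seg.start]
    return out


# --------------------------------------------------------------------------- #
# session generation
# --------------------------------------------------------------------------- #

def _truth_table(cfg: SimConfig, phi_seed: np.ndarray,
                 phi_targets: dict[int, np.ndarray],
                 kappas: dict[int, np.ndarray],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Assemble the per-trial ground-truth table, including log-MEP."""
    m = cfg.mep_model
    phase_at_pulse = _wrap(phi_seed[-1])
    names = {t.source_index: (t.name or f"src{t.source_index}")
             for t in cfg.coupling_targets}
    cols: dict[str, np.ndarray] = {"phase_at_pulse": phase_at_pulse}
    for idx, kap in kappas.items():
        cols[f"kappa_{names[idx]}"] = kap
    # measured-style per-trial iPLV from the model phases (epoch part only)
    n_epoch = phi_seed.shape[0] - 5 if phi_seed.shape[0] > 1000 else phi_seed.shape[0]
    for idx, phi_t in phi_targets.items():
        dphi = phi_seed[:n_epoch] - phi_t[:n_epoch]
        # Im of the mean phasor is the mean sine of the phase difference
        cols[f"iplv_{names[idx]}"] = np.abs(np.mean(np.sin(dphi), axis=0))

    # the first coupling target plays the SMA role, the second the rM1 role
    tgt_idx = [t.source_index for t in cfg.coupling_targets]
    zeros = np.zeros(cfg.n_trials)
    k_sma = kappas[tgt_idx[0]] if tgt_idx else zeros
    k_m1 = kappas[tgt_idx[1]] if len(tgt_idx) > 1 else zeros
    log_clean = (m.beta0 + m.beta_sma * k_sma + m.beta_m1 * k_m1
                 + m.beta_phase * np.cos(phase_at_pulse - m.preferred_phase))
    log_real = log_clean + rng.normal(0, m.noise_sd, cfg.n_trials)
    if not np.all(np.isfinite(np.exp(log_real))):
        raise ValueError("MEP model produced non-finite amplitudes")
    cols["log_mep_clean"] = log_clean
    cols["log_mep"] = log_real
    cols["mep_mv"] = np.exp(log_real)
    return pd.DataFrame(cols)


def simulate_trial_metrics(cfg: SimConfig) -> pd.DataFrame:
    """Fast oscillator-level simulation: per-trial κ, iPLV, phase and MEP only.

    Runs the same phase dynamics and MEP model as :func:`simulate_session`
    but skips lead-field mixing, sensor noise and EMG synthesis.  Intended
    for cohort-scale power and calibration studies.
    """
    rng = np.random.default_rng(cfg.seed)
    n_extra = int(round(5 * cfg.fs_out / 1000.0))
    phi_seed, phi_targets, kappas = _phase_tracks(cfg, rng, n_extra)
    return _truth_table(cfg, phi_seed, phi_targets, kappas, rng)


def simulate_mep_amplitudes(cfg: SimConfig) -> pd.DataFrame:
    """Per-trial MEP amplitudes only (no phase dynamics, no EEG).

    Statistically matched to :func:`simulate_session`'s truth marginals: κ
    per target from the configured Beta laws, pulse phase uniform (the OU
    phase of the full model is uniform modulo 2π at the pulse), log-MEP from
    the linear model plus Gaussian noise.  Used for MEP-level calibration
    studies (e.g. control splits) where connectivity is not needed.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.mep_model
    phase = rng.uniform(-math.pi, math.pi, cfg.n_trials)
    kappas = [_draw_kappa(rng, t.kappa_mean, t.kappa_spread, cfg.n_trials)
              for t in cfg.coupling_targets]
    zeros = np.zeros(cfg.n_trials)
    k_sma = kappas[0] if kappas else zeros
    k_m1 = kappas[1] if len(kappas) > 1 else zeros
    log_clean = (m.beta0 + m.beta_sma * k_sma + m.beta_m1 * k_m1
                 + m.beta_phase * np.cos(phase - m.preferred_phase))
    log_real = log_clean + rng.normal(0, m.noise_sd, cfg.n_trials)
    return pd.DataFrame({"phase_at_pulse": phase, "log_mep": log_real,
                         "mep_mv": np.exp(log_real)})


def simulate_session(cfg: SimConfig, return_sources: bool = False) -> SyntheticSession:
    """Generate a full synthetic EEG-TMS session.

    EEG epochs are 1000 samples at ``fs_out`` covering −1004..−5 ms before
    the pulse; EMG epochs cover −500..+499 ms and contain baseline noise,
    the stimulus artifact and the MEP.  All ground truth (per-trial κ, phase
    at the pulse, noiseless log-MEP) is stored in ``truth``.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_out
    n_src = len(cfg.source_positions)
    n_extra = int(round(5 * fs / 1000.0))

    lf = make_lead_field(cfg.n_sensors, cfg.source_positions,
                         seed=int(rng.integers(2 ** 31)))
    # simulate dipoles along the dominant-gain orientation of each voxel (the
    # component the sensor array actually sees, and the one an orientation-
    # reducing inverse reconstructs)
    from .inverse import reduce_orientation
    gain_scalar = reduce_orientation(lf).gain

    phi_seed, phi_targets, kappas = _phase_tracks(cfg, rng, n_extra)
    truth = _truth_table(cfg, phi_seed, phi_targets, kappas, rng)

    n_times = 1000
    src = np.zeros((n_src, n_times, cfg.n_trials), dtype=np.float32)
    src[0] = cfg.osc_amplitude * np.cos(phi_seed[:n_times])
    for idx, phi_t in phi_targets.items():
        src[idx] = cfg.osc_amplitude * np.cos(phi_t[:n_times])
    if cfg.noise.background_level > 0:
        # every source carries its own 1/f activity, oscillators included:
        # without it, an oscillator's spectral tail is the only content of
        # its voxel outside the μ band, which would make coupling visible at
        # control frequencies where real cortex is background-dominated
        src += (cfg.noise.background_level
                * _one_over_f(rng, (n_src, n_times, cfg.n_trials), fs)
                ).astype(np.float32)

    eeg_data = np.einsum("ij,jtk->itk", gain_scalar, src).astype(np.float32)
    eeg_data += rng.normal(0, cfg.noise.sensor_noise_sd,
                           eeg_data.shape).astype(np.float32)
    time_ms = -1004.0 + np.arange(n_times) * 1000.0 / fs
    eeg = EpochedRecording(eeg_data, fs, time_ms,
                           [f"EEG{i:03d}" for i in range(cfg.n_sensors)], "eeg")

    emg = _synthesize_emg(cfg, truth, rng)

    lf_out = LeadField(gain=lf.gain, positions=lf.positions,
                       sensor_positions=lf.sensor_positions)
    return SyntheticSession(eeg=eeg, emg=emg, leadfield=lf_out, truth=truth,
                            cfg=cfg, sources=src if return_sources else None)


def _synthesize_emg(cfg: SimConfig, truth: pd.DataFrame,
                    rng: np.random.Generator) -> EpochedRecording:
    """EMG at fs_raw (artifact + MEP + noise), decimated to fs_out."""
    q = int(cfg.fs_raw // cfg.fs_out)
    n_raw = int(round(1.0 * cfg.fs_raw))      # 1 s: -500..+499.x ms
    pulse_idx = n_raw // 2
    m = cfg.mep_model
    log_mep = truth["log_mep"].to_numpy()
    n_out = n_raw // q
    data = np.empty((2, n_out, cfg.n_trials), dtype=np.float32)
    for k in range(cfg.n_trials):
        for ch, muscle in enumerate(("FDI", "APB")):
            amp = math.exp(log_mep[k] + rng.normal(0, m.muscle_noise_sd))
            trace = rng.normal(0, cfg.noise.emg_noise_sd, n_raw)
            trace = inject_mep(trace, amp, cfg.mep_latency_ms, cfg.artifact,
                               cfg.fs_raw, pulse_idx)
            if q > 1:
                trace = signal.decimate(trace, q, ftype="fir", zero_phase=True)
            data[ch, :, k] = trace[:n_out]
    time_ms = (np.arange(n_out) - n_out // 2) * 1000.0 / cfg.fs_out
    return EpochedRecording(data, cfg.fs_out, time_ms, ["FDI", "APB"], "emg")


# --------------------------------------------------------------------------- #
# cohorts
# --------------------------------------------------------------------------- #

def cohort_configs(n_subjects: int = 8, n_trials: int = 800, seed: int = 0,
                   base: SimConfig | None = None,
                   f_mu_sd: float = 1.0,
                   beta_scale_sd: float = 0.2) -> list[SimConfig]:
    """Per-subject configs with jittered μ frequency and effect sizes.

    One synthetic "subject" is one session; across subjects the individual
    μ peak is drawn from N(10.5, f_mu_sd²) clipped to [9, 13] and the MEP
    effect sizes are multiplied by N(1, beta_scale_sd²) clipped at 0.
    """
    rng = np.random.default_rng(seed)
    base = base or SimConfig(n_trials=n_trials)
    cfgs = []
    for _ in range(n_subjects):
        f_mu = float(np.clip(rng.normal(10.5, f_mu_sd), 9.0, 13.0))
        scale = max(0.0, rng.normal(1.0, beta_scale_sd))
        m = base.mep_model
        mep = MEPModelConfig(beta0=m.beta0, beta_sma=m.beta_sma * scale,
                             beta_m1=m.beta_m1 * scale,
                             beta_phase=m.beta_phase * scale,
                             preferred_phase=m.preferred_phase,
                             noise_sd=m.noise_sd,
                             muscle_noise_sd=m.muscle_noise_sd)
        cfgs.append(SimConfig(
            n_trials=n_trials, fs_raw=base.fs_raw, fs_out=base.fs_out,
            n_sensors=base.n_sensors,
            source_positions=base.source_positions.copy(),
            f_mu=f_mu,
            coupling_targets=[CouplingTarget(t.source_index, t.phase_offset,
                                             t.kappa_mean, t.kappa_spread,
                                             t.delay_ms, t.name)
                              for t in base.coupling_targets],
            noise=base.noise, mep_model=mep, artifact=base.artifact,
            osc_amplitude=base.osc_amplitude, phase_sd=base.phase_sd,
            phase_tau_s=base.phase_tau_s,
            seed=int(rng.integers(2 ** 31)),
        ))
    return cfgs
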