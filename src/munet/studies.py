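"""Cohort-scale validation studies: parameter recovery, calibration, benchmarks.

These routines generate their own synthetic data (oscillator-level fast path
for cohort-scale runs; full sensor-level sessions where spatial structure
matters), run the corresponding analysis stage, and report recovery or
calibration statistics.  They back both the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sg

from . import phase_model, statesplit
from .directionality import cross_spectra, jackknife_pseudo_z, mpsi
from .inverse import eloreta_filter, reduce_orientation
from .synthgen import (SimConfig, cohort_configs, default_source_grid,
                       make_lead_field, simulate_mep_amplitudes,
                       simulate_trial_metrics)


# --------------------------------------------------------------------------- #
# HC/LC effect recovery and null calibration
# --------------------------------------------------------------------------- #

def _cohort_hc_lc_test(cfgs: list[SimConfig]) -> statesplit.ModulationResult:
    """Run the network-level HC/LC modulation analysis on one cohort."""
    meps, hc, lc = [], [], []
    for cfg in cfgs:
        df = simulate_trial_metrics(cfg)
        split_sma = statesplit.median_split(df["iplv_lSMA"].to_numpy())
        split_m1 = statesplit.median_split(df["iplv_rM1"].to_numpy())
        ts = statesplit.network_trials({"lSMA": split_sma, "rM1": split_m1})
        meps.append(df["mep_mv"].to_numpy())
        hc.append(ts.hc_network)
        lc.append(ts.lc_network)
    return statesplit.modulation(meps, hc, lc)


def effect_recovery_study(n_cohorts: int = 100, n_subjects: int = 8,
                          n_trials: int = 800, seed: int = 0,
                          null: bool = False, alpha: float = 0.05) -> dict:
    """HC_network vs LC_network modulation across simulated cohorts.

    With the default effect sizes the one-tailed paired t-test should reject
    in most cohorts; with ``null=True`` all MEP effect sizes are zero and
    the rejection rate estimates the test's false-positive level.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    diffs = []
    for _ in range(n_cohorts):
        base = SimConfig(n_trials=n_trials)
        if null:
            base.mep_model.beta_sma = 0.0
            base.mep_model.beta_m1 = 0.0
            base.mep_model.beta_phase = 0.0
        cfgs = cohort_configs(n_subjects, n_trials, seed=int(rng.integers(2 ** 31)),
                              base=base)
        res = _cohort_hc_lc_test(cfgs)
        rejections += (res.p is not None and res.p < alpha
                       and res.mean_diff > 0)
        diffs.append(res.mean_diff)
    return {"rejection_rate": rejections / n_cohorts,
            "mean_modulation_diff": float(np.mean(diffs)),
            "n_cohorts": n_cohorts}


def control_split_study(n_cohorts: int = 200, n_subjects: int = 8,
                        n_trials: int = 800, seed: int = 0,
                        alpha: float = 0.05) -> dict:
    """False-positive rates of the first/second-half and even/odd controls."""
    rng = np.random.default_rng(seed)
    rej = {"first_vs_second": 0, "even_vs_odd": 0}
    for _ in range(n_cohorts):
        cfgs = cohort_configs(n_subjects, n_trials,
                              seed=int(rng.integers(2 ** 31)))
        meps = [simulate_mep_amplitudes(c)["mep_mv"].to_numpy() for c in cfgs]
        res = statesplit.control_split_tests(meps)
        for name in rej:
            rej[name] += res[name]["p"] < alpha
    return {name: count / n_cohorts for name, count in rej.items()} | {
        "n_cohorts": n_cohorts}


def overlap_study(n_cohorts: int = 20, n_trials: int = 800,
                  seed: int = 0) -> float:
    """Median HC-trial overlap percentage between the two cROI splits."""
    rng = np.random.default_rng(seed)
    overlaps = []
    for _ in range(n_cohorts):
        cfg = SimConfig(n_trials=n_trials, seed=int(rng.integers(2 ** 31)))
        df = simulate_trial_metrics(cfg)
        ts = statesplit.network_trials({
            "lSMA": statesplit.median_split(df["iplv_lSMA"].to_numpy()),
            "rM1": statesplit.median_split(df["iplv_rM1"].to_numpy())})
        overlaps.append(ts.overlap_percent)
    return float(np.median(overlaps))


# --------------------------------------------------------------------------- #
# model-selection recovery
# --------------------------------------------------------------------------- #

def model_selection_study(n_runs: int = 200, n_trials: int = 800,
                          seed: int = 0, generator: str = "full") -> dict:
    """AIC model-recovery rates for a given generating model.

    ``generator``: 'full' (network + phase effects at the generator's
    default sizes) or 'constant' (pure noise around an intercept).
    """
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name in phase_model.MODEL_NAMES}
    m = SimConfig().mep_model      # default effect sizes
    for _ in range(n_runs):
        iplv = np.column_stack([rng.beta(2, 2, n_trials),
                                rng.beta(2, 2, n_trials)])
        phase = rng.uniform(-np.pi, np.pi, n_trials)
        if generator == "full":
            y = (m.beta0 + m.beta_sma * iplv[:, 0] + m.beta_m1 * iplv[:, 1]
                 + m.beta_phase * np.cos(phase - m.preferred_phase)
                 + rng.normal(0, m.noise_sd, n_trials))
        else:
            y = m.beta0 + rng.normal(0, m.noise_sd, n_trials)
        cmp_ = phase_model.fit_models(y, iplv, phase)
        counts[cmp_.preferred] += 1
    return {"rates": {k: v / n_runs for k, v in counts.items()},
            "n_runs": n_runs}


# --------------------------------------------------------------------------- #
# phase-prediction benchmark
# --------------------------------------------------------------------------- #

def _pink(n: int, rng: np.random.Generator, fs: float) -> np.ndarray:
    w = rng.normal(0, 1, 2 * n)
    spec = np.fft.rfft(w)
    fr = np.fft.rfftfreq(2 * n, 1 / fs)
    spec[1:] /= np.sqrt(fr[1:])
    spec[0] = 0
    x = np.fft.irfft(spec)[:n]
    return x / x.std()


def phase_benchmark(n_trials: int = 500, snr_db: float | None = 10.0,
                    seed: int = 0, fs: float = 1000.0) -> float:
    """Circular mean absolute error of the pre-pulse phase estimator.

    Trials are 500 ms cosines at random μ frequencies and phases, plus pink
    noise at the requested SNR (signal power 0.5 vs noise power
    0.5/10^(snr/10)); ``snr_db=None`` runs noiseless.
    """
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_trials):
        f = rng.uniform(9.5, 12.5)
        phi0 = rng.uniform(-np.pi, np.pi)
        t = np.arange(-499, 1) / fs
        x = np.cos(2 * np.pi * f * t + phi0)
        if snr_db is not None:
            noise_sd = np.sqrt(0.5 / 10 ** (snr_db / 10))
            x = x + noise_sd * _pink(len(t), rng, fs)
        est = phase_model.estimate_phase_at_pulse(x, f, fs)
        errs.append(abs(np.angle(np.exp(1j * (est.phase - phi0)))))
    return float(np.mean(errs))


# --------------------------------------------------------------------------- #
# eLORETA localization
# --------------------------------------------------------------------------- #

def eloreta_localization_study(n_leadfields: int = 10, n_sensors: int = 32,
                               n_sources: int = 50, seed: int = 0) -> float:
    """Fraction of voxels whose noiseless lead-field column localizes home."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_leadfields):
        pos = default_source_grid(n_sources - 3,
                                  seed=int(rng.integers(2 ** 31)))
        lf = make_lead_field(n_sensors, pos, seed=int(rng.integers(2 ** 31)))
        red = reduce_orientation(lf)
        filt = eloreta_filter(red)
        H = np.eye(n_sensors) - 1.0 / n_sensors
        Lc = H @ red.gain
        argmax = np.argmax(np.abs(filt.weights @ Lc), axis=0)
        hits += int(np.sum(argmax == np.arange(red.n_sources)))
        total += red.n_sources
    return hits / total


# --------------------------------------------------------------------------- #
# MPSI benchmarks
# --------------------------------------------------------------------------- #

def _mu_band_noise(rng: np.random.Generator, n_seg: int, n_samp: int,
                   fs: float, margin: int = 200) -> np.ndarray:
    sos = sg.butter(4, [8, 13], btype="bandpass", fs=fs, output="sos")
    base = sg.sosfilt(sos, rng.normal(0, 1, (n_seg, n_samp + margin)), axis=-1)
    return base / base.std()


def mpsi_delay_study(n_runs: int = 100, delay_ms: float = 10.0,
                     n_channels: int = 3, n_segments: int = 100,
                     seed: int = 0, fs: float = 1000.0) -> dict:
    """Detection rate of a constructed delay (pseudo-Z > 2, correct sign)."""
    freqs = np.arange(9.0, 14.0)
    delay = int(round(delay_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_runs):
        base = _mu_band_noise(rng, n_segments, 1000, fs)
        X = np.stack([base[:, 100:1100]
                      + rng.normal(0, 0.5, (n_segments, 1000))
                      for _ in range(n_channels)], axis=1)
        Y = np.stack([base[:, 100 - delay: 1100 - delay]
                      + rng.normal(0, 0.5, (n_segments, 1000))
                      for _ in range(n_channels)], axis=1)
        res = jackknife_pseudo_z(cross_spectra(X, Y, freqs, fs))
        detected += (res.psi > 0 and res.pseudo_z is not None
                     and res.pseudo_z > 2.0)
    return {"detection_rate": detected / n_runs, "n_runs": n_runs}


def mpsi_bivariate_agreement(seed: int = 0, fs: float = 1000.0) -> float:
    """|MPSI(n=m=1) − direct coherency PSI| on one μ-band delayed pair."""
    freqs = np.arange(9.0, 14.0)
    rng = np.random.default_rng(seed)
    base = _mu_band_noise(rng, 100, 1000, fs)
    x = base[:, 100:1100] + rng.normal(0, 0.5, (100, 1000))
    y = base[:, 90:1090] + rng.normal(0, 0.5, (100, 1000))
    cs = cross_spectra(x[:, None, :], y[:, None, :], freqs, fs)
    win = np.hanning(1000)
    bins = np.round(freqs * 1000 / fs).astype(int)
    fx = np.fft.rfft(x * win, axis=-1)[:, bins]
    fy = np.fft.rfft(y * win, axis=-1)[:, bins]
    coh = (np.mean(fx * np.conj(fy), axis=0)
           / np.sqrt(np.mean(np.abs(fx) ** 2, axis=0)
                     * np.mean(np.abs(fy) ** 2, axis=0)))
    direct = float(np.sum(np.imag(np.conj(coh[:-1]) * coh[1:])))
    return abs(mpsi(cs) - direct)


# --------------------------------------------------------------------------- #
# iPLV identities
# --------------------------------------------------------------------------- #

def iplv_identities(seed: int = 0, T: int = 1000,
                    n_draws: int = 10_000) -> dict:
    """Desk checks of the iPLV formula: lag identities and the uniform null."""
    from .connectivity import iplv_trial

    rng = np.random.default_rng(seed)
    ph = rng.uniform(-np.pi, np.pi, T)
    quarter = np.linspace(0, 40 * np.pi, T)
    null_vals = [iplv_trial(rng.uniform(-np.pi, np.pi, T),
                            rng.uniform(-np.pi, np.pi, T))
                 for _ in range(n_draws)]
    return {
        "zero_lag": iplv_trial(ph, 0.5 * ph + 0.5 * ph),   # mixed copy, lag 0
        "quarter_lag": iplv_trial(quarter, quarter - np.pi / 2),
        "uniform_null_mean": float(np.mean(null_vals)),
        "uniform_null_expected": float(1 / np.sqrt(np.pi * T)),
    }
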