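"""EEG/EMG preprocessing: epoching, artifact screening, μ-component selection,
and single-trial MEP quantification.

Visual steps of typical TMS-EEG pipelines are replaced here by automatic,
documented criteria: independent components are retained when (a) their
spectrum has a local maximum in the 9-13 Hz μ range, (b) the μ-band to
β-band power ratio is at least 5, and (c) their source projection peaks
inside a motor-cortex mask.  MEPs are scored per trial as the peak-to-peak
EMG amplitude after detrending, 50 Hz removal and subtraction of a fitted
exponential stimulus artifact; log amplitudes of the two hand muscles are
combined by PCA and the first component used as the trial-level response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .containers import EpochedRecording, SpatialFilter

MU_RANGE = (9.0, 13.0)
BETA_BAND = (15.0, 30.0)


@dataclass
class SpectralProfile:
    """Per-subject analysis frequencies derived from the μ-component spectra."""

    f_mu: float
    mu_band: tuple[float, float]
    beta_band: tuple[float, float] = BETA_BAND
    theta_f: float = 5.0
    beta_f: float = 21.0

    def __post_init__(self) -> None:
        if not MU_RANGE[0] <= self.f_mu <= MU_RANGE[1]:
            raise ValueError("f_mu must lie in the 9-13 Hz range")
        if self.mu_band[1] > self.beta_band[0]:
            raise ValueError("mu and beta bands must not overlap")


@dataclass
class ICSelection:
    kept_indices: list[int]
    peak_freqs: dict[int, float]
    mu_beta_ratio: dict[int, float]
    argmax_position: dict[int, np.ndarray]


@dataclass
class MEPTable:
    """Per-trial MEP amplitudes, log values, PC1 score and QC flags."""

    table: pd.DataFrame
    rejected: dict[int, str] = field(default_factory=dict)
    pc1_variance_explained: float = float("nan")

    def __post_init__(self) -> None:
        if "p2p_fdi" in self.table and np.any(self.table["p2p_fdi"] < 0):
            raise ValueError("peak-to-peak amplitudes must be non-negative")


# --------------------------------------------------------------------------- #
# epoching / decimation
# --------------------------------------------------------------------------- #

def epoch_and_downsample(raw: np.ndarray, fs_raw: float,
                         pulse_samples: np.ndarray,
                         window_ms: tuple[float, float],
                         fs_out: float,
                         labels: list[str] | None = None,
                         role: str = "eeg") -> EpochedRecording:
    """Anti-alias decimate a continuous recording and cut stimulus-locked epochs.

    ``raw`` is (n_channels, n_samples) at ``fs_raw``; ``pulse_samples`` are
    pulse onsets in raw-sampling indices.  The output has exactly
    round((w_end − w_start)·fs_out/1000) samples per epoch, the first sample
    at ``w_start`` ms relative to each pulse.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if fs_raw % fs_out:
        raise ValueError("fs_raw must be an integer multiple of fs_out")
    q = int(fs_raw // fs_out)
    dec = signal.decimate(raw, q, ftype="fir", zero_phase=True) if q > 1 else raw
    w_start, w_end = window_ms
    n_samp = int(round((w_end - w_start) * fs_out / 1000.0))
    epochs = np.empty((raw.shape[0], n_samp, len(pulse_samples)))
    for k, p in enumerate(np.asarray(pulse_samples)):
        i0 = int(round(p / q + w_start * fs_out / 1000.0))
        if i0 < 0 or i0 + n_samp > dec.shape[1]:
            raise ValueError(f"window for pulse {k} extends past recording bounds")
        epochs[:, :, k] = dec[:, i0: i0 + n_samp]
    time_ms = w_start + np.arange(n_samp) * 1000.0 / fs_out
    labels = labels or [f"ch{i}" for i in range(raw.shape[0])]
    return EpochedRecording(epochs, fs_out, time_ms, labels, role)


# --------------------------------------------------------------------------- #
# bad channel / trial detection
# --------------------------------------------------------------------------- #

def detect_bad(epochs: EpochedRecording,
               z_thresh: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Flag channels and trials with outlying robust variance z-scores.

    The variance of each channel (pooled over time and trials) and of each
    trial (pooled over channels and time) is standardized by median/MAD
    across the respective cohort; entries with |z| > ``z_thresh`` are
    flagged.  The input is never modified.
    """
    if epochs.n_channels < 4 or epochs.n_trials < 10:
        raise ValueError("need at least 4 channels and 10 trials")

    def robust_z(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad <= 0:
            mad = np.std(v) or 1.0
        return (v - med) / mad

    ch_var = epochs.data.var(axis=(1, 2))
    tr_var = epochs.data.var(axis=(0, 1))
    bad_channels = np.flatnonzero(np.abs(robust_z(ch_var)) > z_thresh)
    bad_trials = np.flatnonzero(np.abs(robust_z(tr_var)) > z_thresh)
    if len(bad_channels) == epochs.n_channels:
        raise ValueError("all channels flagged: data unusable")
    return bad_channels, bad_trials


# --------------------------------------------------------------------------- #
# μ-component selection and reconstruction
# --------------------------------------------------------------------------- #

def run_ica(epochs: EpochedRecording, n_pcs: int = 35, n_ics: int | None = None,
            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """FastICA in the subspace of the largest principal vectors.

    Trials are concatenated in time, the data reduced to ``n_pcs`` principal
    components, and FastICA run on that subspace.  Returns
    ``(timecourses (n_ics, n_times, n_trials), topographies (n_ch, n_ics))``.
    """
    import warnings

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    n_ch, n_t, n_tr = epochs.data.shape
    X = epochs.data.reshape(n_ch, n_t * n_tr).T      # samples × channels
    n_comp = min(n_pcs, n_ch)
    ica = FastICA(n_components=n_ics or n_comp, whiten="unit-variance",
                  random_state=seed, max_iter=1000, tol=1e-3)
    with warnings.catch_warnings():
        # the near-Gaussian background subspace has no unique rotation, so
        # full FastICA convergence is not expected (nor needed: kept
        # components are the strongly non-Gaussian oscillatory ones)
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(X)                     # samples × n_ics
    topo = ica.mixing_                               # channels × n_ics
    tc = S.T.reshape(-1, n_t, n_tr)
    return tc, topo


def _ic_spectrum(tc: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch spectrum of an IC, averaging across trials."""
    n_t = tc.shape[0]
    f, p = signal.welch(tc, fs=fs, axis=0, nperseg=min(n_t, 1024))
    return f, p.mean(axis=-1)


def _has_local_max(f: np.ndarray, p: np.ndarray,
                   lo: float, hi: float) -> tuple[bool, float]:
    band = (f >= lo) & (f <= hi)
    idx = np.flatnonzero(band)
    if idx.size < 1:
        return False, float("nan")
    i_pk = idx[np.argmax(p[idx])]
    # require a genuine local maximum (not a band-edge slope)
    if 0 < i_pk < len(p) - 1 and p[i_pk] >= p[i_pk - 1] and p[i_pk] >= p[i_pk + 1]:
        return True, float(f[i_pk])
    return False, float(f[i_pk])


def select_mu_components(ic_timecourses: np.ndarray, ic_topographies: np.ndarray,
                         fs: float, spatial_filter: SpatialFilter,
                         motor_mask: np.ndarray,
                         ratio_thresh: float = 5.0
                         ) -> tuple[ICSelection, SpectralProfile]:
    """Keep ICs with a μ peak, μ/β power ratio ≥ 5 and motor-localized topography.

    ``ic_timecourses`` is (n_ics, n_times, n_trials); ``ic_topographies`` is
    (n_channels, n_ics).  The individual μ frequency is the μ-peak frequency
    of the kept IC with the strongest μ-band power.
    """
    motor_mask = np.asarray(motor_mask, dtype=int)
    kept: list[int] = []
    peak_freqs: dict[int, float] = {}
    ratios: dict[int, float] = {}
    argmax_pos: dict[int, np.ndarray] = {}
    mu_power: dict[int, float] = {}
    topo_c = ic_topographies - ic_topographies.mean(axis=0, keepdims=True)
    src_proj = np.abs(spatial_filter.weights @ topo_c)   # n_sources × n_ics
    for i in range(ic_timecourses.shape[0]):
        f, p = _ic_spectrum(ic_timecourses[i], fs)
        ok_peak, f_pk = _has_local_max(f, p, *MU_RANGE)
        peak_freqs[i] = f_pk
        if not ok_peak:
            continue
        mu_band = (f >= f_pk - 2) & (f <= f_pk + 2)
        beta_band = (f >= BETA_BAND[0]) & (f <= BETA_BAND[1])
        ratio = p[mu_band].mean() / max(p[beta_band].mean(), 1e-30)
        ratios[i] = float(ratio)
        if ratio < ratio_thresh:
            continue
        j_max = int(np.argmax(src_proj[:, i]))
        if j_max not in motor_mask:
            continue
        kept.append(i)
        argmax_pos[i] = j_max
        mu_power[i] = float(p[mu_band].mean())
    if not kept:
        raise ValueError("no μ component: no IC satisfies all selection criteria")
    strongest = max(kept, key=lambda i: mu_power[i])
    f_mu = float(np.clip(peak_freqs[strongest], *MU_RANGE))
    profile = SpectralProfile(f_mu=f_mu, mu_band=(f_mu - 2, f_mu + 2))
    return ICSelection(kept, peak_freqs, ratios, argmax_pos), profile


def reconstruct_clean(ic_timecourses: np.ndarray, ic_topographies: np.ndarray,
                      kept: list[int] | np.ndarray, fs: float,
                      time_ms: np.ndarray, labels: list[str]
                      ) -> EpochedRecording:
    """Rebuild channel-level signals from the kept ICs (topography ⊗ timecourse)."""
    kept = sorted(set(int(k) for k in np.asarray(kept, dtype=int)))
    if not kept:
        raise ValueError("kept IC set is empty")
    if ic_topographies.shape[1] != ic_timecourses.shape[0]:
        raise ValueError("topographies and timecourses are inconsistent")
    data = np.einsum("ci,itk->ctk", ic_topographies[:, kept],
                     ic_timecourses[kept])
    return EpochedRecording(data, fs, time_ms, labels, "eeg")


# --------------------------------------------------------------------------- #
# MEP extraction
# --------------------------------------------------------------------------- #

def _remove_artifact(trace: np.ndarray, t_ms: np.ndarray,
                     artifact_window: tuple[float, float]) -> tuple[np.ndarray, bool]:
    """Fit A·exp(−t/τ)+B in the artifact window, subtract its extrapolation."""
    m = (t_ms >= artifact_window[0]) & (t_ms <= artifact_window[1])
    tw, yw = t_ms[m], trace[m]

    def model(t, a, tau, b):
        return a * np.exp(-t / tau) + b

    try:
        a0 = yw[0] - yw[-1]
        p, _ = optimize.curve_fit(model, tw, yw, p0=[a0, 5.0, yw[-1]],
                                  bounds=([-np.inf, 0.1, -np.inf],
                                          [np.inf, 100.0, np.inf]),
                                  maxfev=2000)
    except (RuntimeError, ValueError):
        return trace, True
    post = t_ms >= 0
    out = trace.copy()
    out[post] = out[post] - model(t_ms[post], *p) + p[2]
    return out, False


def extract_mep(emg: EpochedRecording,
                mep_window: tuple[float, float] = (20.0, 45.0),
                artifact_window: tuple[float, float] = (2.0, 15.0),
                pre_emg_thresh_uv: float = 50.0) -> MEPTable:
    """Score single-trial MEPs from epoched EMG (mV).

    Per trial and muscle: linear detrend fitted on the pre-pulse samples,
    50 Hz notch, exponential artifact fit on ``artifact_window`` and
    subtraction of its extrapolation, then peak-to-peak amplitude within
    ``mep_window``.  Trials whose pre-pulse RMS exceeds
    ``pre_emg_thresh_uv`` (µV) are rejected as pre-activated; trials with a
    non-convergent artifact fit are kept but flagged.
    """
    if mep_window[0] <= artifact_window[1]:
        raise ValueError("mep_window must be disjoint from and after artifact_window")
    t_ms = emg.time_ms
    pre = t_ms < 0
    mep_m = (t_ms >= mep_window[0]) & (t_ms <= mep_window[1])
    b_notch, a_notch = signal.iirnotch(50.0, Q=30.0, fs=emg.fs)
    rows = []
    rejected: dict[int, str] = {}
    if emg.n_channels != 2:
        raise ValueError("expected a two-muscle (FDI, APB) EMG recording")
    for k in range(emg.n_trials):
        p2p = []
        pre_rms = []
        flagged = False
        for ch in range(2):
            tr = emg.data[ch, :, k].astype(float)
            coef = np.polyfit(t_ms[pre], tr[pre], 1)
            tr = tr - np.polyval(coef, t_ms)
            # artifact fit precedes the notch: the notch transient of the
            # multi-mV stimulus step would otherwise distort the exponential
            tr, fb = _remove_artifact(tr, t_ms, artifact_window)
            tr = signal.filtfilt(b_notch, a_notch, tr)
            flagged |= fb
            p2p.append(float(tr[mep_m].max() - tr[mep_m].min()))
            pre_rms.append(float(np.sqrt(np.mean(tr[pre] ** 2))))
        if max(pre_rms) * 1000.0 > pre_emg_thresh_uv:
            rejected[k] = "pre-stimulus activity"
            continue
        rows.append({"trial": k, "p2p_fdi": p2p[0], "p2p_apb": p2p[1],
                     "artifact_fit_failed": flagged})
    if len(rows) < 10:
        raise ValueError("fewer than 10 valid trials after rejection")
    df = pd.DataFrame(rows).set_index("trial")
    df["log_fdi"] = np.log(df["p2p_fdi"])
    df["log_apb"] = np.log(df["p2p_apb"])
    try:
        pc1, var_exp = mep_pc1(df["log_fdi"].to_numpy(), df["log_apb"].to_numpy())
    except ValueError:      # degenerate (constant) amplitudes: keep the table
        pc1, var_exp = np.zeros(len(df)), float("nan")
    df["pc1_score"] = pc1
    df["linear_amp"] = np.exp((df["log_fdi"] + df["log_apb"]) / 2)  # geometric mean
    return MEPTable(table=df, rejected=rejected, pc1_variance_explained=var_exp)


def mep_pc1(log_fdi: np.ndarray, log_apb: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of the two-muscle log-amplitude table.

    Scores are sign-fixed so they correlate positively with the mean log
    amplitude.  Returns ``(scores, variance_explained)``.
    """
    log_fdi = np.asarray(log_fdi, dtype=float)
    log_apb = np.asarray(log_apb, dtype=float)
    if len(log_fdi) < 10:
        raise ValueError("need at least 10 valid trials")
    X = np.column_stack([log_fdi, log_apb])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("zero variance in both muscles")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[0]
    var_exp = float(s[0] ** 2 / np.sum(s ** 2))
    mean_log = X.mean(axis=1)
    if np.dot(scores - scores.mean(), mean_log - mean_log.mean()) < 0:
        scores = -scores
    return scores, var_exp
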