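"""Directed coupling between multivariate voxel patches: the multivariate
phase slope index (MPSI) with jackknife pseudo-Z standardization.

For multichannel signals X (n channels) and Y (m channels) with segment-wise
cross-spectra, the whitened cross-spectral matrix is

    C(f) = S_XX(f)^(-1/2) · S_XY(f) · S_YY(f)^(-1/2)

and the MPSI over a frequency band B with resolution δf is

    ψ = Σ_{f ∈ B} Im tr( C(f)ᴴ C(f + δf) )

The sign convention here is positive ψ ⇒ X temporally leads Y (for n = m = 1
this reduces exactly to the bivariate phase slope index on the complex
coherency).  Significance is assessed as a pseudo-Z: ψ divided by its
jackknife standard deviation across estimation segments; group-level
aggregation multiplies the mean individual pseudo-Z by √N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class VoxelPatch:
    """Voxels within ``radius_mm`` of a centre position (MNI mm)."""

    members: np.ndarray
    centre: np.ndarray
    radius_mm: float

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class CrossSpectra:
    """Per-segment windowed Fourier coefficients for two channel blocks.

    ``coeffs`` has shape (n_segments, n_x + n_y, n_freqs); the first ``n_x``
    rows of the channel axis belong to X.  Cross-spectral matrices are mean
    outer products across segments.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    n_x: int
    segment_len_s: float

    @property
    def n_segments(self) -> int:
        return self.coeffs.shape[0]

    def mean_cross_spectrum(self, exclude: int | None = None) -> np.ndarray:
        """S(f) per frequency, (n_freqs, n_chan, n_chan), optionally jackknifed."""
        z = self.coeffs
        if exclude is not None:
            z = np.delete(z, exclude, axis=0)
        # S[f] = mean_seg z[:, :, f] z[:, :, f]^H
        return np.einsum("saf,sbf->fab", z, z.conj()) / z.shape[0]


@dataclass
class DirectionalityResult:
    psi: float
    jackknife_sd: float
    pseudo_z: float | None
    pair: tuple[str, str]
    band: tuple[float, float]
    degenerate: bool = False     # True when the jackknife SD collapsed to 0

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "psi": self.psi,
                "jackknife_sd": self.jackknife_sd, "pseudo_z": self.pseudo_z,
                "band_hz": list(self.band), "degenerate": self.degenerate}


def select_voxel_patch(positions: np.ndarray, centre: np.ndarray,
                       radius_mm: float = 4.0) -> VoxelPatch:
    """All voxels within ``radius_mm`` (Euclidean) of ``centre``."""
    positions = np.asarray(positions, dtype=float)
    centre = np.asarray(centre, dtype=float)
    if positions.size == 0:
        raise ValueError("empty position list")
    d = np.linalg.norm(positions - centre, axis=1)
    members = np.flatnonzero(d <= radius_mm)
    if members.size == 0:
        raise ValueError(
            f"no voxel within {radius_mm} mm of the centre; increase the radius")
    return VoxelPatch(members=members, centre=centre, radius_mm=radius_mm)


def cross_spectra(x: np.ndarray, y: np.ndarray, freqs: np.ndarray,
                  fs: float) -> CrossSpectra:
    """Hann-windowed Fourier coefficients of segmented data at given frequencies.

    ``x`` and ``y`` are (n_segments, n_channels, n_samples); segments are
    typically the concatenated 1 s pre-stimulus epochs of the analyzed trial
    class.  ``freqs`` must be multiples of the native resolution fs/n_samples
    (1 Hz for 1 s segments at 1 kHz).
    """
    x = np.atleast_3d(np.asarray(x, dtype=float))
    y = np.atleast_3d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of segments")
    n_seg, _, n_samp = x.shape
    if n_seg < 8:
        raise ValueError("need at least 8 segments for a stable jackknife")
    df = fs / n_samp
    freqs = np.asarray(freqs, dtype=float)
    bins = freqs / df
    if np.any(np.abs(bins - np.round(bins)) > 1e-6):
        raise ValueError("requested frequencies are not multiples of fs/n_samples")
    bins = np.round(bins).astype(int)
    win = np.hanning(n_samp)
    z = np.concatenate([x, y], axis=1) * win[None, None, :]
    spec = np.fft.rfft(z, axis=-1)[:, :, bins]
    return CrossSpectra(coeffs=spec, freqs=freqs, n_x=x.shape[1],
                        segment_len_s=n_samp / fs)


def _inv_sqrt_psd(S: np.ndarray, reg: float = 1e-8) -> np.ndarray:
    """Regularized inverse matrix square root of a Hermitian PSD matrix.

    Scalar blocks are inverted exactly (they cannot be rank-deficient unless
    zero), so the n = m = 1 case reduces to the plain coherency-based phase
    slope index with no regularization error.
    """
    n = S.shape[0]
    if n == 1:
        return np.array([[1.0 / np.sqrt(max(S[0, 0].real, 1e-300))]])
    Sr = S + reg * (np.trace(S).real / n) * np.eye(n)
    vals, vecs = np.linalg.eigh(Sr)
    vals = np.maximum(vals.real, 1e-30)
    return (vecs / np.sqrt(vals)) @ vecs.conj().T


def _psi_from_cross(S: np.ndarray, n_x: int, band_idx: np.ndarray) -> float:
    """ψ from per-frequency cross-spectral matrices S (n_freqs, n_chan, n_chan)."""
    C = []
    for f in band_idx:
        Sxx = S[f][:n_x, :n_x]
        Syy = S[f][n_x:, n_x:]
        Sxy = S[f][:n_x, n_x:]
        C.append(_inv_sqrt_psd(Sxx) @ Sxy @ _inv_sqrt_psd(Syy))
    psi = 0.0
    for i in range(len(C) - 1):
        psi += np.trace(C[i].conj().T @ C[i + 1]).imag
    return float(psi)


def mpsi(cs: CrossSpectra, band: tuple[float, float] | None = None,
         delta_f: float = 1.0) -> float:
    """Multivariate phase slope index over ``band`` (defaults to all frequencies).

    Positive values mean the X block temporally leads the Y block.
    """
    freqs = cs.freqs
    if band is None:
        band_idx = np.arange(len(freqs))
    else:
        band_idx = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if len(band_idx) < 2:
        raise ValueError("band must cover at least 2 analysis frequencies")
    step = np.diff(freqs[band_idx])
    if not np.allclose(step, delta_f):
        raise ValueError("analysis frequencies must be spaced by delta_f")
    S = cs.mean_cross_spectrum()
    return _psi_from_cross(S, cs.n_x, band_idx)


def jackknife_pseudo_z(cs: CrossSpectra, band: tuple[float, float] | None = None,
                       delta_f: float = 1.0,
                       pair: tuple[str, str] = ("X", "Y")) -> DirectionalityResult:
    """MPSI with leave-one-segment-out jackknife SD and pseudo-Z score.

    jackknife SD = sqrt((N−1)/N · Σ_i (ψ₍₋ᵢ₎ − mean ψ₍₋ᵢ₎)²); pseudo-Z is
    the full-sample ψ divided by that SD, undefined (flagged) when SD = 0.
    """
    freqs = cs.freqs
    if band is None:
        band_idx = np.arange(len(freqs))
    else:
        band_idx = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if len(band_idx) < 2:
        raise ValueError("band must cover at least 2 analysis frequencies")
    n = cs.n_segments
    psi_full = _psi_from_cross(cs.mean_cross_spectrum(), cs.n_x, band_idx)
    loo = np.array([_psi_from_cross(cs.mean_cross_spectrum(exclude=i),
                                    cs.n_x, band_idx) for i in range(n)])
    sd = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    band_out = (float(freqs[band_idx[0]]), float(freqs[band_idx[-1]]))
    if sd <= 1e-10 * max(abs(psi_full), 1.0):   # identical segments
        return DirectionalityResult(psi_full, 0.0, None, pair, band_out,
                                    degenerate=True)
    return DirectionalityResult(psi_full, sd, psi_full / sd, pair, band_out)


def group_z(pseudo_zs: np.ndarray) -> tuple[float, float]:
    """Group-level Z = √N · mean(individual pseudo-Zs), with two-sided normal p."""
    z = np.asarray(pseudo_zs, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one subject")
    Z = float(np.sqrt(z.size) * z.mean())
    p = float(2 * stats.norm.sf(abs(Z)))
    return Z, p
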