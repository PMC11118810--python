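"""Preprocessing tests: epoching, bad-data screening, IC selection, MEPs."""

import numpy as np
import pytest

from munet.containers import EpochedRecording
from munet.preprocess import (detect_bad, epoch_and_downsample, extract_mep,
                              mep_pc1, reconstruct_clean, select_mu_components)
from munet.synthgen import ArtifactConfig, inject_mep


def _emg_epochs(traces: np.ndarray, fs: float = 1000.0) -> EpochedRecording:
    n = traces.shape[1]
    t_ms = (np.arange(n) - n // 2) * 1000.0 / fs
    return EpochedRecording(traces, fs, t_ms, ["FDI", "APB"], "emg")


class TestEpochAndDownsample:
    def test_window_geometry_matches_protocol(self):
        # 5 kHz recording, 1 kHz output, (-1004, -4) ms window
        fs_raw, fs_out = 5000.0, 1000.0
        n_pulses = 12
        pulses = 6000 + np.arange(n_pulses) * 10_000
        raw = np.random.default_rng(0).normal(0, 1, (3, int(pulses[-1] + 5000)))
        rec = epoch_and_downsample(raw, fs_raw, pulses, (-1004, -4), fs_out)
        assert rec.data.shape == (3, 1000, n_pulses)
        assert rec.time_ms[0] == -1004.0
        assert rec.fs == fs_out

    def test_in_band_amplitude_preserved(self):
        fs_raw, fs_out = 5000.0, 1000.0
        t = np.arange(100_000) / fs_raw
        raw = np.sin(2 * np.pi * 10 * t)[None, :]
        rec = epoch_and_downsample(raw, fs_raw, np.array([60_000]),
                                   (-1004, -4), fs_out)
        amp = (rec.data.max() - rec.data.min()) / 2
        assert np.isclose(amp, 1.0, rtol=0.01)

    def test_above_nyquist_attenuated(self):
        fs_raw, fs_out = 5000.0, 1000.0
        t = np.arange(100_000) / fs_raw
        raw = np.sin(2 * np.pi * 800 * t)[None, :]
        rec = epoch_and_downsample(raw, fs_raw, np.array([60_000]),
                                   (-1004, -4), fs_out)
        atten = 20 * np.log10(np.abs(rec.data).max() / 1.0)
        assert atten < -20

    def test_out_of_bounds_pulse_named(self):
        raw = np.zeros((2, 10_000))
        with pytest.raises(ValueError, match="pulse 0"):
            epoch_and_downsample(raw, 5000.0, np.array([1000]), (-1004, -4),
                                 1000.0)


class TestDetectBad:
    def _epochs(self, data):
        t = np.arange(data.shape[1]).astype(float)
        return EpochedRecording(data, 1000.0, t,
                                [f"c{i}" for i in range(data.shape[0])], "eeg")

    def test_homogeneous_noise_rarely_flagged(self):
        flags = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ch, tr = detect_bad(self._epochs(rng.normal(0, 1, (16, 200, 30))))
            flags += (len(ch) > 0) or (len(tr) > 0)
        assert flags <= 1

    def test_scaled_channel_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, (16, 200, 30))
        data[5] *= 100
        ch, _ = detect_bad(self._epochs(data))
        assert 5 in ch

    def test_step_artifact_trial_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (16, 200, 30))
        data[:, 100:, 7] += 1000.0          # 1 mV step in µV units
        _, tr = detect_bad(self._epochs(data))
        assert 7 in tr

    def test_input_not_mutated(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (16, 200, 30))
        rec = self._epochs(data.copy())
        detect_bad(rec)
        assert np.array_equal(rec.data, data)


class TestSelectMuComponents:
    """Constructed-IC cases for the three μ-selection rules."""

    def _setup(self):
        from munet.inverse import eloreta_filter, reduce_orientation
        from munet.synthgen import default_source_grid, make_lead_field

        pos = default_source_grid(10)
        red = reduce_orientation(make_lead_field(16, pos, seed=0))
        filt = eloreta_filter(red)
        return red, filt

    def _timecourses(self, kind, rng, n_t=1000, n_tr=20, fs=1000.0):
        t = np.arange(n_t) / fs
        if kind == "mu":        # clean 11 Hz with a little noise
            x = np.cos(2 * np.pi * 11 * t[:, None]
                       + rng.uniform(0, 2 * np.pi, n_tr))
            return x + 0.05 * rng.normal(size=(n_t, n_tr))
        if kind == "beta":      # 21 Hz dominant
            x = np.cos(2 * np.pi * 21 * t[:, None]
                       + rng.uniform(0, 2 * np.pi, n_tr))
            return x + 0.05 * rng.normal(size=(n_t, n_tr))
        return rng.normal(size=(n_t, n_tr))   # white noise

    def test_rules_keep_mu_reject_beta_and_noise(self):
        rng = np.random.default_rng(0)
        red, filt = self._setup()
        n = red.n_sensors
        Lc = (np.eye(n) - 1 / n) @ red.gain
        tc = np.stack([self._timecourses(k, rng)
                       for k in ("mu", "beta", "noise")])
        # topographies: μ IC looks like the lM1 source; others like source 5
        topo = np.column_stack([Lc[:, 0], Lc[:, 5], Lc[:, 5]])
        sel, prof = select_mu_components(tc, topo, 1000.0, filt,
                                         motor_mask=np.array([0, 1, 2]))
        assert sel.kept_indices == [0]
        assert np.isclose(prof.f_mu, 11.0, atol=1.0)

    def test_motor_localization_required(self):
        rng = np.random.default_rng(1)
        red, filt = self._setup()
        n = red.n_sensors
        Lc = (np.eye(n) - 1 / n) @ red.gain
        tc = self._timecourses("mu", rng)[None, :, :]
        topo = Lc[:, [8]]                     # localizes far from the mask
        with pytest.raises(ValueError, match="no μ component"):
            select_mu_components(tc, topo, 1000.0, filt,
                                 motor_mask=np.array([0, 1, 2]))

    def test_mu_beta_ratio_rule(self):
        rng = np.random.default_rng(2)
        red, filt = self._setup()
        n = red.n_sensors
        Lc = (np.eye(n) - 1 / n) @ red.gain
        t = np.arange(1000) / 1000.0
        # equal-power 11 Hz and 21 Hz: ratio ~1, below the threshold of 5
        x = (np.cos(2 * np.pi * 11 * t[:, None] + rng.uniform(0, 7, 20))
             + np.cos(2 * np.pi * 21 * t[:, None] + rng.uniform(0, 7, 20)))
        with pytest.raises(ValueError, match="no μ component"):
            select_mu_components(x[None], Lc[:, [0]], 1000.0, filt,
                                 motor_mask=np.array([0, 1, 2]))


class TestReconstructClean:
    def test_keeping_all_ics_restores_subspace(self):
        rng = np.random.default_rng(0)
        topo = rng.normal(size=(8, 5))
        tc = rng.normal(size=(5, 100, 7))
        full = np.einsum("ci,itk->ctk", topo, tc)
        rec = reconstruct_clean(tc, topo, list(range(5)), 1000.0,
                                np.arange(100).astype(float),
                                [f"c{i}" for i in range(8)])
        assert np.allclose(rec.data, full, atol=1e-10)

    def test_single_ic_rank_one_per_trial(self):
        rng = np.random.default_rng(1)
        topo = rng.normal(size=(8, 5))
        tc = rng.normal(size=(5, 100, 3))
        rec = reconstruct_clean(tc, topo, [2], 1000.0,
                                np.arange(100).astype(float),
                                [f"c{i}" for i in range(8)])
        for k in range(3):
            assert np.linalg.matrix_rank(rec.data[:, :, k]) == 1

    def test_order_invariance_and_empty_error(self):
        rng = np.random.default_rng(2)
        topo = rng.normal(size=(8, 4))
        tc = rng.normal(size=(4, 50, 2))
        args = (1000.0, np.arange(50).astype(float),
                [f"c{i}" for i in range(8)])
        a = reconstruct_clean(tc, topo, [1, 2], *args)
        b = reconstruct_clean(tc, topo, [2, 1], *args)
        assert np.array_equal(a.data, b.data)
        with pytest.raises(ValueError, match="empty"):
            reconstruct_clean(tc, topo, [], *args)


class TestExtractMep:
    fs = 1000.0
    art = ArtifactConfig()

    def _make(self, amps, noise_sd=0.0, seed=0, n_trials=None):
        rng = np.random.default_rng(seed)
        amps = np.atleast_1d(amps)
        n_trials = n_trials or max(12, len(amps))
        if len(amps) == 1:
            amps = np.repeat(amps, n_trials)
        n = 1000
        data = np.zeros((2, n, len(amps)))
        for k, a in enumerate(amps):
            for ch in range(2):
                tr = rng.normal(0, noise_sd, n) if noise_sd else np.zeros(n)
                data[ch, :, k] = inject_mep(tr, a, 25.0, self.art, self.fs,
                                            n // 2)
        return _emg_epochs(data)

    def test_noiseless_round_trip_within_five_percent(self):
        for a in (0.05, 0.2, 1.0, 5.0):
            mt = extract_mep(self._make(a))
            meas = mt.table[["p2p_fdi", "p2p_apb"]].to_numpy().mean()
            assert abs(meas - a) / a < 0.05

    def test_recovery_grid_at_10uV_noise(self):
        # ≥0.2 mV: within 5%; below that the noise peak-to-peak floor
        # (~2·4σ over the window) dominates and only a bias bound holds
        for a in (0.2, 0.5, 1.0, 2.0, 5.0):
            mt = extract_mep(self._make(a, noise_sd=0.010, seed=1))
            meas = mt.table[["p2p_fdi", "p2p_apb"]].to_numpy().mean()
            assert abs(meas - a) / a < 0.05
        mt = extract_mep(self._make(0.05, noise_sd=0.010, seed=1))
        meas = mt.table[["p2p_fdi", "p2p_apb"]].to_numpy().mean()
        assert abs(meas - 0.05) < 0.04

    def test_artifact_only_overlap_recovery(self):
        # strong artifact (A=5 mV, tau=5 ms) plus a small 0.5 mV MEP
        mt = extract_mep(self._make(0.5))
        meas = mt.table[["p2p_fdi", "p2p_apb"]].to_numpy().mean()
        assert abs(meas - 0.5) / 0.5 < 0.10

    def test_tonic_preactivation_rejected(self):
        rng = np.random.default_rng(3)
        data = np.zeros((2, 1000, 12))
        for k in range(12):
            for ch in range(2):
                tr = rng.normal(0, 0.001, 1000)
                if k == 4:
                    tr[:500] += 0.2 * np.sin(2 * np.pi * 120
                                             * np.arange(1000)[:500] / 1000.0)
                data[ch, :, k] = inject_mep(tr, 1.0, 25.0, self.art,
                                            self.fs, 500)
        mt = extract_mep(self._make(1.0, noise_sd=0.001))
        assert mt.rejected == {}
        mt = extract_mep(_emg_epochs(data), pre_emg_thresh_uv=50.0)
        assert mt.rejected.get(4) == "pre-stimulus activity"
        assert 4 not in mt.table.index


class TestMepPc1:
    def test_collinear_columns_explain_everything(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        scores, ve = mep_pc1(x, x)
        assert np.isclose(ve, 1.0)
        assert np.corrcoef(scores, x)[0, 1] > 0.999

    def test_independent_columns_split_variance(self):
        rng = np.random.default_rng(1)
        _, ve = mep_pc1(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))
        assert abs(ve - 0.5) < 0.02

    def test_highly_correlated_columns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 2000)
        y = x + 0.05 * rng.normal(0, 1, 2000)   # r ≈ 0.999
        scores, ve = mep_pc1(x, y)
        assert ve >= 0.99
        # sign convention: positively correlated with the mean log amplitude
        assert np.corrcoef(scores, (x + y) / 2)[0, 1] > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mep_pc1(np.ones(20), np.ones(20))
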