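"""Analytic-signal, iPLV, seed-map and cROI tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from munet.connectivity import (ConnectivityMap, croi_trial_values,
                                extract_crois, group_map, iplv_trial,
                                narrowband_analytic, seed_map)
from munet.synthgen import LSMA_MNI, RM1_MNI


class TestNarrowbandAnalytic:
    fs = 1000.0

    def test_in_band_sinusoid_envelope_and_phase(self):
        t = np.arange(1000) / self.fs
        x = np.sin(2 * np.pi * 11.0 * t)
        ana = narrowband_analytic(x, 11.0, self.fs)
        env = ana.envelope
        assert np.all(np.abs(env - 1.0) < 0.02)
        # phase advances by 2π·f per second
        dphi = np.unwrap(ana.phase)
        slope = np.polyfit(t, dphi, 1)[0]
        assert np.isclose(slope, 2 * np.pi * 11.0, rtol=0.01)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(1000) / self.fs
        ana_in = narrowband_analytic(np.sin(2 * np.pi * 11 * t), 11.0, self.fs)
        ana_out = narrowband_analytic(np.sin(2 * np.pi * 16 * t), 11.0, self.fs)
        assert ana_out.envelope.mean() < 0.1 * ana_in.envelope.mean()

    def test_ar_padding_beats_zero_padding_at_edges(self):
        # envelope error in the outer 64 ms of 11 Hz + pink-noise epochs,
        # referenced against filtering the (normally unobserved) long signal
        from scipy import signal as sg
        rng = np.random.default_rng(0)
        wins, n = 0, 60
        n_long, lo = 6000, 2500
        sos = sg.butter(4, [10, 12], btype="bandpass", fs=self.fs, output="sos")
        n_pad = 1600
        for i in range(n):
            t = np.arange(n_long) / self.fs
            w = rng.normal(0, 1, n_long)
            spec = np.fft.rfft(w)
            fr = np.fft.rfftfreq(n_long, 1 / self.fs)
            spec[1:] /= np.sqrt(fr[1:])
            pink = np.fft.irfft(spec, n_long)
            x = np.cos(2 * np.pi * 11 * t + rng.uniform(0, 2 * np.pi))
            x = x + 0.5 * pink / pink.std()
            seg = x[lo: lo + 1000]
            ref = np.abs(sg.hilbert(sg.sosfiltfilt(sos, x))[lo: lo + 1000])
            ana_ar = narrowband_analytic(seg, 11.0, self.fs)
            zp = np.abs(sg.hilbert(
                sg.sosfiltfilt(sos, np.pad(seg, n_pad)))[n_pad: -n_pad])
            edge = np.r_[0:64, 936:1000]
            err_ar = np.abs(ana_ar.envelope[edge] - ref[edge]).mean()
            err_zp = np.abs(zp[edge] - ref[edge]).mean()
            wins += err_ar < err_zp
        assert wins > n / 2       # AR padding wins in the median

    def test_constant_signal_falls_back_to_reflection(self):
        ana = narrowband_analytic(np.zeros(1000), 11.0, self.fs)
        assert ana.ar_fallback

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="short"):
            narrowband_analytic(np.zeros(50), 11.0, self.fs)


class TestIplvTrial:
    def test_quarter_cycle_lag_gives_one(self):
        ph = np.linspace(0, 40 * np.pi, 1000)
        assert np.isclose(iplv_trial(ph, ph - np.pi / 2), 1.0)

    def test_zero_lag_gives_exact_zero(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert iplv_trial(ph, ph) == 0.0

    def test_uniform_null_matches_monte_carlo_expectation(self):
        # E|Im(mean phasor)| = 1/sqrt(pi*T) for iid uniform phases
        rng = np.random.default_rng(1)
        T = 1000
        vals = [iplv_trial(rng.uniform(-np.pi, np.pi, T),
                           rng.uniform(-np.pi, np.pi, T))
                for _ in range(10_000)]
        assert np.isclose(np.mean(vals), 1 / np.sqrt(np.pi * T), rtol=0.05)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-np.pi, np.pi))
    def test_common_offset_and_swap_invariance(self, seed, off):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, 200)
        b = rng.uniform(-np.pi, np.pi, 200)
        base = iplv_trial(a, b)
        assert np.isclose(iplv_trial(a + off, b + off), base, atol=1e-12)
        assert np.isclose(iplv_trial(b, a), base, atol=1e-12)

    def test_nan_phases_rejected(self):
        ph = np.zeros(10)
        bad = ph.copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            iplv_trial(ph, bad)


class TestSeedMap:
    def test_coupled_vs_independent_vs_zerolag(self):
        # constructed phase signals: target A locked at pi/2, B independent,
        # C a zero-lag copy of the seed
        rng = np.random.default_rng(5)
        n_t, n_tr = 1000, 40
        t = np.arange(n_t) / 1000.0
        phases = 2 * np.pi * 11 * t[None, :, None] + rng.uniform(
            0, 2 * np.pi, (1, 1, n_tr))
        seed_sig = np.cos(phases[0])
        locked = np.cos(phases[0] - np.pi / 2)
        # independent oscillator: same centre frequency but diffusing phase
        drift = np.cumsum(rng.normal(0, 0.3, (n_t, n_tr)), axis=0)
        indep = np.cos(2 * np.pi * 11 * t[:, None]
                       + rng.uniform(0, 2 * np.pi, (1, n_tr)) + drift)
        zerolag = 3.0 * seed_sig
        src = np.stack([seed_sig, locked, indep, zerolag])
        pos = np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0], [0, 0, 40]], float)
        cmap, trials = seed_map(src, 0, 11.0, 1000.0, pos)
        assert cmap.values[1] > 0.95
        assert cmap.values[3] < 0.05          # volume-conduction immunity
        assert cmap.values[2] < 0.5
        assert cmap.values[0] == 0.0          # seed excluded by convention
        assert trials.shape == (4, n_tr)

    def test_map_value_monotone_in_coupling(self):
        from munet.synthgen import CouplingTarget, SimConfig, simulate_trial_metrics
        from munet.synthgen import default_source_grid
        means = []
        for kap in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = SimConfig(
                n_trials=300, n_sensors=16,
                source_positions=default_source_grid(10),
                coupling_targets=[CouplingTarget(1, kappa_mean=kap,
                                                 kappa_spread=0.0, name="t")],
                seed=8)
            means.append(simulate_trial_metrics(cfg)["iplv_t"].mean())
        assert np.all(np.diff(means) > 0)

    def test_too_few_trials_rejected(self):
        src = np.zeros((2, 1000, 10))
        with pytest.raises(ValueError, match="20 trials"):
            seed_map(src, 0, 11.0, 1000.0, np.zeros((2, 3)))


class TestGroupMap:
    def _map(self, vals):
        pos = np.column_stack([np.arange(len(vals)) * 20.0,
                               np.zeros(len(vals)), np.zeros(len(vals))])
        return ConnectivityMap(np.asarray(vals, float), pos, 0, pos[0], 11.0)

    def test_single_subject_identity_and_mean(self):
        a = self._map([0, 0.5, 0.3])
        assert np.allclose(group_map([a]).values, a.values)
        b = self._map([0, 0.1, 0.5])
        g = group_map([a, b])
        assert np.allclose(g.values, [0, 0.3, 0.4])
        assert g.level == "group"

    def test_subject_order_invariance(self):
        a, b, c = self._map([0, .5, .3]), self._map([0, .1, .2]), self._map([0, .9, .4])
        assert np.allclose(group_map([a, b, c]).values,
                           group_map([c, a, b]).values)

    def test_grid_mismatch_rejected(self):
        a = self._map([0, 0.5, 0.3])
        b = self._map([0, 0.5, 0.3, 0.1])
        with pytest.raises(ValueError, match="grid"):
            group_map([a, b])


class TestExtractCrois:
    def test_recovers_two_coupled_patches(self, patch_session):
        ses, sources, ps = patch_session
        pos = ses.cfg.source_positions
        cmap, _ = seed_map(sources, 0, ses.cfg.f_mu, 1000.0, pos,
                           pad="reflect", trial_average="coherent")
        rois = extract_crois(cmap, quantile=0.65, min_size=3)
        assert len(rois) == 2
        cents = np.array([r.centroid for r in rois])
        d_sma = np.linalg.norm(cents - LSMA_MNI, axis=1).min()
        d_rm1 = np.linalg.norm(cents - RM1_MNI, axis=1).min()
        assert d_sma < 10 and d_rm1 < 10

    def test_seed_adjacent_cluster_excluded(self):
        vals = np.array([0.0, 0.9, 0.9, 0.8, 0.8])
        pos = np.array([[0, 0, 0], [5, 0, 0], [8, 0, 0],    # inside 20 mm
                        [50, 0, 0], [55, 0, 0]], float)
        cmap = ConnectivityMap(vals, pos, 0, pos[0], 11.0)
        rois = extract_crois(cmap, quantile=0.5, min_size=2,
                             seed_exclusion_mm=20.0)
        assert len(rois) == 1
        assert set(rois[0].members) == {3, 4}

    def test_uniform_random_map_rarely_yields_crois(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-70, 70, (50, 3))
        hits = 0
        for _ in range(20):
            cmap = ConnectivityMap(rng.uniform(0, 1, 50), pos, 0, pos[0], 11.0)
            try:
                extract_crois(cmap)     # defaults: q=0.95, min_size=5
                hits += 1
            except ValueError:
                pass
        assert hits <= 2

    def test_centroid_is_iplv_weighted(self):
        vals = np.array([0.0, 0.2, 0.8])
        pos = np.array([[0, 0, 0], [40, 0, 0], [50, 0, 0]], float)
        cmap = ConnectivityMap(vals, pos, 0, pos[0], 11.0)
        roi = extract_crois(cmap, quantile=0.0, min_size=2)[0]
        expected = (0.2 * pos[1] + 0.8 * pos[2]) / 1.0
        assert np.allclose(roi.centroid, expected)


class TestCroiTrialValues:
    def test_patch_average_tracks_truth_coupling(self, patch_session):
        from scipy.stats import spearmanr
        ses, sources, ps = patch_session
        pos = ses.cfg.source_positions
        cmap, _ = seed_map(sources, 0, ses.cfg.f_mu, 1000.0, pos,
                           pad="reflect", trial_average="coherent")
        rois = extract_crois(cmap, quantile=0.65, min_size=3)
        roi_sma = min(rois, key=lambda r: np.linalg.norm(r.centroid - LSMA_MNI))
        vals = croi_trial_values(sources, 0, roi_sma, ses.cfg.f_mu, 1000.0,
                                 pad="reflect")
        # compare against the generator's per-trial phase-locking truth,
        # averaged over the patch members
        truth_iplv = np.mean(
            [ses.truth[f"iplv_sma{i}"] for i in range(1, 1 + ps)], axis=0)
        assert spearmanr(vals, truth_iplv).statistic > 0.3


class TestFrequencyControls:
    def test_theta_beta_maps_do_not_show_mu_coupling(self, patch_session):
        # μ-coupled voxels must look null when mapped at 5 Hz and 21 Hz
        ses, sources, ps = patch_session
        pos = ses.cfg.source_positions
        mu, _ = seed_map(sources, 0, ses.cfg.f_mu, 1000.0, pos,
                         pad="reflect", trial_average="coherent")
        coupled = np.arange(1, 1 + 2 * ps)
        bg = np.arange(1 + 2 * ps, len(pos))
        for f_ctl, max_ratio in ((5.0, 0.2), (21.0, 0.3)):
            ctl, _ = seed_map(sources, 0, f_ctl, 1000.0, pos,
                              pad="reflect", trial_average="coherent")
            null_level = np.quantile(ctl.values[bg], 0.95)
            # coupled voxels near the background null, far below the μ map
            assert ctl.values[coupled].mean() < 2 * max(null_level, 0.05)
            assert ctl.values[coupled].mean() < max_ratio * mu.values[coupled].mean()
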