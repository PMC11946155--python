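"""Generator fidelity: noise spectra, task timing, ERP insertion, couplings."""

import numpy as np
import pytest
from scipy import signal

from pawnpipe import (GroundTruth, OscillationBand, ErpComponent, Coupling,
                      SessionConfig, amplitude_spectrum, default_ground_truth,
                      derive_rng, expected_noise_psd, expected_oscillation_psd,
                      generate_band_noise, generate_pink_noise,
                      generate_session, generate_white_noise,
                      participant_truth)
from pawnpipe.spectral import expected_mean_amplitude, noise_psd_from_mean_amplitude


class TestPinkNoise:
    def test_zero_power_gives_zero_series(self):
        x = generate_pink_noise(1024, 1000.0, 0.0, 7)
        assert np.all(x == 0.0)

    def test_loglog_slope_minus_one(self):
        pows = []
        for s in range(50):
            x = generate_pink_noise(2**16, 1000.0, 4.0, derive_rng(s, "pink-test"))
            f, p = signal.periodogram(x, fs=1000.0)
            pows.append(p)
        pm = np.mean(pows, axis=0)
        m = (f >= 2) & (f <= 100)
        slope = np.polyfit(np.log(f[m]), np.log(pm[m]), 1)[0]
        assert abs(slope + 1.0) < 0.05

    def test_power_ratio_2hz_vs_4hz(self):
        pows = []
        for s in range(100):
            x = generate_pink_noise(2**16, 1000.0, 4.0, derive_rng(s, "pink-ratio"))
            f, p = signal.periodogram(x, fs=1000.0)
            pows.append(p)
        pm = np.mean(pows, axis=0)
        i2, i4 = np.argmin(np.abs(f - 2)), np.argmin(np.abs(f - 4))
        assert abs(pm[i2] / pm[i4] - 2.0) < 0.2

    def test_zero_mean_and_invalid_args(self):
        x = generate_pink_noise(4096, 1000.0, 2.0, 0)
        assert abs(x.mean()) < 1e-9
        with pytest.raises(ValueError):
            generate_pink_noise(1, 1000.0, 1.0, 0)
        with pytest.raises(ValueError):
            generate_pink_noise(100, 1000.0, -1.0, 0)


class TestWhiteNoise:
    def test_zero_power(self):
        assert np.all(generate_white_noise(100, 1000.0, 0.0, 1) == 0)

    def test_variance_psd_identity(self):
        x = generate_white_noise(10**6, 1000.0, 1.0, 3)
        assert abs(x.var() / 500.0 - 1.0) < 0.05

    def test_flat_spectrum_slope(self):
        pows = []
        for s in range(50):
            x = generate_white_noise(2**15, 1000.0, 1.0, derive_rng(s, "wn"))
            f, p = signal.periodogram(x, fs=1000.0)
            pows.append(p)
        pm = np.mean(pows, axis=0)
        m = (f >= 2) & (f <= 100)
        slope = np.polyfit(np.log(f[m]), np.log(pm[m]), 1)[0]
        assert abs(slope) < 0.05


def test_band_noise_variance_and_concentration():
    x = generate_band_noise(2**17, 1000.0, 10.0, 2.0, 3.5, 11)
    assert abs(x.std() / 3.5 - 1.0) < 0.05
    f, p = signal.periodogram(x, fs=1000.0)
    inband = (f >= 7) & (f <= 13)
    assert p[inband].sum() / p.sum() > 0.95


class TestEvents:
    def test_trial_count_two_blocks(self):
        cfg = SessionConfig(n_channels=2)
        truth = default_ground_truth(2)
        s = generate_session(cfg, truth, seed=5)
        assert len(s.events) == 300
        assert (s.events.code == "go").sum() == 150

    def test_fixed_onset_asynchrony_within_block(self):
        cfg = SessionConfig(n_channels=2, n_blocks=2)
        s = generate_session(cfg, default_ground_truth(2), seed=5)
        for b, grp in s.events.groupby("block"):
            assert np.all(np.diff(grp.onset_sample) == cfg.soa_samples)

    def test_seed_reproducibility(self):
        cfg = SessionConfig(n_channels=2, n_go_per_block=10, n_nogo_per_block=10,
                            n_blocks=1)
        t = default_ground_truth(2)
        a = generate_session(cfg, t, seed=9)
        b = generate_session(cfg, t, seed=9)
        assert np.array_equal(a.recording.data, b.recording.data)
        assert a.events.equals(b.events)
        c = generate_session(cfg, t, seed=10)
        assert not np.array_equal(a.recording.data, c.recording.data)


class TestSessionComposition:
    def test_additivity_of_parts(self):
        cfg = SessionConfig(n_channels=3, n_go_per_block=10, n_nogo_per_block=10,
                            n_blocks=1)
        s = generate_session(cfg, default_ground_truth(3), seed=2, keep_parts=True)
        total = sum(s.parts.values())
        assert np.allclose(total, s.recording.data, atol=1e-12)

    def test_noiseless_erp_reconstruction(self):
        C = 2
        truth = GroundTruth(
            pink_power_at_1hz=np.zeros(C), white_power=np.zeros(C), bands=[],
            erp_components=[ErpComponent("P3", "go", 300.0, 80.0, 10.0, +1,
                                         np.ones(C))],
            couplings=[], omission_rate=0.0, commission_rate=0.0)
        cfg = SessionConfig(n_channels=C, n_go_per_block=10, n_nogo_per_block=10,
                            n_blocks=1)
        s = generate_session(cfg, truth, seed=4)
        go = s.events[s.events.code == "go"]
        seg = np.stack([s.recording.data[:, o:o + 500] for o in go.onset_sample])
        erp = seg.mean(axis=0)
        peak_idx = np.argmax(erp[0])
        assert abs(erp[0, peak_idx] - 10.0) < 1e-9
        assert abs(peak_idx - 300) <= 1

    def test_unknown_coupling_target_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(pink_power_at_1hz=[1.0], white_power=[0.1], bands=[],
                        erp_components=[], couplings=[
                            Coupling("pink", "nope", "go", +1, 0.5)])

    def test_coupling_drives_trialwise_template_scale(self):
        """With alpha -> P3 coupling, the per-trial template scale follows the
        measured prestimulus alpha amplitude (corr > 0.3 over 300 trials)."""
        C = 3
        corr = []
        for seed in range(5):
            base = default_ground_truth(C)
            truth = GroundTruth(
                pink_power_at_1hz=base.pink_power_at_1hz,
                white_power=base.white_power,
                bands=base.bands,
                erp_components=[c for c in base.erp_components if c.condition == "go"],
                couplings=[Coupling("A1", "P3b", "go", +1, 0.5)])
            s = generate_session(SessionConfig(n_channels=C), truth, seed=seed)
            a = s.internals["source_amplitudes"]["A1"]
            sc = s.internals["component_scales"][("go", "P3b")]
            corr.append(np.corrcoef(a, sc)[0, 1])
        assert np.median(corr) > 0.3


class TestSpectralGroundTruth:
    def _session_spectra(self, truth, seed, n_ch=4):
        cfg = SessionConfig(n_channels=n_ch, n_blocks=2)
        s = generate_session(cfg, truth, seed=seed)
        segs = np.stack([s.recording.data[:, o - 500:o]
                         for o in s.events.onset_sample])
        freqs, amp = amplitude_spectrum(segs)
        return freqs, amp.mean(axis=(0, 1))

    def test_noise_only_spectrum_matches_p_over_f_plus_w(self):
        truth = GroundTruth(pink_power_at_1hz=np.full(4, 10.0),
                            white_power=np.full(4, 0.3), bands=[],
                            erp_components=[], couplings=[])
        freqs, mean_amp = self._session_spectra(truth, seed=21)
        psd_est = noise_psd_from_mean_amplitude(mean_amp, 500, 1000.0)
        psd_true = expected_noise_psd(truth, freqs)
        m = (freqs >= 2) & (freqs <= 24)
        assert np.all(np.abs(psd_est[m] / psd_true[m] - 1.0) < 0.15)

    def test_full_spectrum_matches_window_aware_expectation(self):
        truth = GroundTruth(
            pink_power_at_1hz=np.full(4, 10.0), white_power=np.full(4, 0.3),
            bands=[OscillationBand("alpha", 10.0, 2.0, 3.5),
                   OscillationBand("beta", 18.0, 4.0, 1.5)],
            erp_components=[], couplings=[])
        freqs, mean_amp = self._session_spectra(truth, seed=3)
        fine = np.linspace(0.25, 45.0, 1800)
        psd = expected_noise_psd(truth, fine) + expected_oscillation_psd(truth, fine)
        expected = expected_mean_amplitude(freqs, fine, psd, 500, 1000.0)
        m = (freqs >= 2) & (freqs <= 24)
        assert np.all(np.abs(mean_amp[m] / expected[m] - 1.0) < 0.15)


def test_participant_jitter_scales_amplitudes(rng):
    base = default_ground_truth(4)
    scales = []
    for i in range(200):
        t = participant_truth(base, derive_rng(1, "jit", i), 0.2)
        scales.append(t.band("A1").rms_uv / base.band("A1").rms_uv)
    scales = np.asarray(scales)
    assert np.all(scales > 0)
    assert abs(np.median(np.log(scales))) < 0.05
    assert abs(np.std(np.log(scales)) - 0.2) < 0.04


def test_session_config_validation():
    with pytest.raises(ValueError):
        SessionConfig(fs=-1)
    with pytest.raises(ValueError):
        SessionConfig(soa_ms=1100.5)  # non-integer sample count at fs=1000
    with pytest.raises(ValueError):
        SessionConfig(n_blocks=0)
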