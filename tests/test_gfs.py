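import numpy as np
import pytest
from scipy import signal

from gfstrack.core_io import ConfigurationError, Recording
from gfstrack.gfs import (
    GFSConfig,
    band_average,
    band_psd_series,
    bandpass,
    common_average_reference,
    gfs_spectrum,
    make_epochs,
    remove_dc,
    remove_eog_pca,
    subject_gfs_series,
)
from gfstrack.synthetic import GroupConfig, StimulusEvent, StimulusScript, simulate_eeg
from oracles import band_psd_direct, gfs_closed_form


def _eeg(samples, rate=256.0, roles=None):
    n = samples.shape[0]
    labels = [f"ch{i}" for i in range(n)]
    return Recording("s", labels, roles or ["EEG"] * n, rate, samples)


class TestCommonAverageReference:
    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.normal(size=256)
        rec = _eeg(np.vstack([x, -x]))
        out = common_average_reference(rec)
        assert np.allclose(out.samples, rec.samples)

    def test_common_offset_removed(self):
        rec = _eeg(np.full((5, 100), 3.7))
        assert np.allclose(common_average_reference(rec).samples, 0.0)

    def test_column_means_zero(self, rng):
        rec = _eeg(rng.normal(size=(12, 512)))
        out = common_average_reference(rec)
        assert np.max(np.abs(out.samples.mean(axis=0))) < 1e-10

    def test_non_eeg_channels_untouched(self, rng):
        x = rng.normal(size=(3, 100))
        rec = _eeg(x.copy(), roles=["EEG", "EEG", "GSR"])
        out = common_average_reference(rec)
        assert np.array_equal(out.samples[2], x[2])

    def test_single_eeg_channel_rejected(self, rng):
        rec = _eeg(rng.normal(size=(2, 100)), roles=["EEG", "GSR"])
        with pytest.raises(ConfigurationError):
            common_average_reference(rec)


class TestRemoveDC:
    @pytest.mark.parametrize("x,expected_zero", [
        (np.full((1, 64), 5.0), True),            # constant -> zero
        (np.sin(np.arange(64) * 2 * np.pi / 64)[None, :], False),
    ])
    def test_channel_means_removed(self, x, expected_zero):
        out = remove_dc(_eeg(x))
        assert abs(out.samples.mean()) < 1e-12
        if expected_zero:
            assert np.allclose(out.samples, 0.0)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(2560) / 256.0
        rec = _eeg(np.vstack([np.sin(2 * np.pi * 30 * t), np.zeros_like(t)]))
        out = bandpass(rec, 1.0, 55.0)
        mid = slice(512, 2048)
        ratio = np.std(out.samples[0, mid]) / np.std(rec.samples[0, mid])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_slow_drift_removed(self):
        t = np.arange(2560) / 256.0
        rec = _eeg(np.vstack([np.sin(2 * np.pi * 0.2 * t), np.zeros_like(t)]))
        out = bandpass(rec, 1.0, 55.0)
        mid = slice(512, 2048)
        assert np.std(out.samples[0, mid]) < 0.1 * np.std(rec.samples[0, mid])

    def test_zero_in_zero_out(self):
        rec = _eeg(np.zeros((2, 512)))
        assert np.allclose(bandpass(rec, 1.0, 55.0).samples, 0.0)

    def test_invalid_band_rejected(self, rng):
        rec = _eeg(rng.normal(size=(2, 512)))
        with pytest.raises(ConfigurationError):
            bandpass(rec, 55.0, 1.0)
        with pytest.raises(ConfigurationError):
            bandpass(rec, 1.0, 200.0)  # above Nyquist

    def test_stopband_attenuation_contract(self):
        # >= 20 dB at low/2 and 2*high for the default design
        sos = signal.butter(4, [1.0, 55.0], btype="bandpass", fs=256.0, output="sos")
        for f in (0.5, 110.0):
            w, h = signal.sosfreqz(sos, worN=[2 * np.pi * f / 256.0])
            att_db = -20 * np.log10(np.abs(h[0]) ** 2)  # filtfilt squares |H|
            assert att_db >= 20.0


class TestRemoveEOGPCA:
    def test_uncorrelated_eeg_passes_through(self, rng):
        x = rng.normal(size=(6, 2048))
        eog = rng.normal(size=2048)
        rec = _eeg(np.vstack([x, eog]), roles=["EEG"] * 6 + ["EOG_V"])
        out = remove_eog_pca(rec, 0.7)
        assert np.allclose(out.samples[:6], x, atol=1e-8)

    def test_blink_component_removed(self, rng):
        n = 4096
        blink = np.zeros(n)
        for s in range(200, n - 200, 600):
            blink[s:s + 80] += np.hanning(80)
        eeg = rng.normal(size=(8, n))
        gains = rng.uniform(0.5, 1.5, size=8)
        contaminated = eeg + gains[:, None] * blink
        rec = _eeg(np.vstack([contaminated, blink + 0.01 * rng.normal(size=n)]),
                   roles=["EEG"] * 8 + ["EOG_V"])
        out = remove_eog_pca(rec, 0.7)
        veog = rec.samples[8]
        corrs = [abs(np.corrcoef(out.samples[i], veog)[0, 1]) for i in range(8)]
        assert max(corrs) < 0.7

    def test_threshold_one_is_identity(self, rng):
        x = rng.normal(size=(4, 512))
        rec = _eeg(np.vstack([x, rng.normal(size=512)]), roles=["EEG"] * 4 + ["EOG_V"])
        out = remove_eog_pca(rec, 1.0)
        assert np.allclose(out.samples[:4], x, atol=1e-8)

    def test_missing_eog_channel_instructs_skip(self, rng):
        rec = _eeg(rng.normal(size=(4, 512)))
        with pytest.raises(ConfigurationError, match="skip"):
            remove_eog_pca(rec, 0.7)


class TestMakeEpochs:
    @pytest.mark.parametrize("dur_s,rate,expected", [
        (10.0, 256.0, 9),     # 10 s, 2-s epochs, 50% overlap
        (2.0, 256.0, 1),      # exactly one epoch
        (313.0, 2048.0, 312), # a 5-min-13-s clip
    ])
    def test_epoch_count(self, dur_s, rate, expected):
        rec = _eeg(np.zeros((1, int(dur_s * rate))), rate=rate)
        grid = make_epochs(rec, 2.0, 0.5)
        assert grid.n_epochs == expected

    def test_count_formula_general(self, rng):
        rec = _eeg(np.zeros((1, 1000)), rate=100.0)
        grid = make_epochs(rec, 2.0, 0.25)
        L, step = 200, 150
        assert grid.n_epochs == (1000 - L) // step + 1
        assert np.all(np.diff(grid.start_indices) == step)

    def test_too_short_recording_rejected(self):
        rec = _eeg(np.zeros((1, 100)), rate=256.0)
        with pytest.raises(ConfigurationError, match="shorter"):
            make_epochs(rec, 2.0, 0.5)

    def test_center_times(self):
        rec = _eeg(np.zeros((1, 2560)), rate=256.0)
        grid = make_epochs(rec, 2.0, 0.5)
        assert np.allclose(grid.center_times()[:3], [1.0, 2.0, 3.0])


class TestGFSSpectrum:
    def test_identical_channels_give_one(self, rng):
        x = rng.normal(size=512)
        spec = gfs_spectrum(np.tile(x, (6, 1)), 256.0)
        defined = ~np.isnan(spec.gfs)
        assert np.allclose(spec.gfs[defined], 1.0, atol=1e-9)
        assert np.all(spec.eigenvalues[defined, 1] < 1e-9 * spec.eigenvalues[defined, 0])

    def test_quadrature_phases_give_zero(self):
        # 4 equal-amplitude channels at phases 0/90/180/270 form an
        # isotropic cross in the complex plane at that bin
        L, fbin = 256, 16
        n = np.arange(L)
        phases = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
        epoch = np.vstack([np.cos(2 * np.pi * fbin * n / L + p) for p in phases])
        spec = gfs_spectrum(epoch, 256.0)
        assert spec.gfs[fbin] == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_oracle(self):
        # 100 random epochs against the explicit-DFT / characteristic-
        # quadratic reference
        taper = signal.get_window("hann", 512, fftbins=True)
        worst = 0.0
        for seed in range(100):
            epoch = np.random.default_rng(seed).normal(size=(12, 512))
            spec = gfs_spectrum(epoch, 256.0)
            ref = gfs_closed_form(epoch, taper)
            both = ~np.isnan(spec.gfs) & ~np.isnan(ref)
            worst = max(worst, np.max(np.abs(spec.gfs[both] - ref[both])))
        assert worst < 1e-10

    def test_bounded_and_invariant(self, rng):
        epoch = rng.normal(size=(8, 256))
        spec = gfs_spectrum(epoch, 256.0)
        g = spec.gfs[~np.isnan(spec.gfs)]
        assert np.all((g >= 0) & (g <= 1))
        perm = rng.permutation(8)
        assert np.allclose(gfs_spectrum(epoch[perm], 256.0).gfs, spec.gfs,
                           atol=1e-12, equal_nan=True)
        assert np.allclose(gfs_spectrum(epoch * -3.2, 256.0).gfs, spec.gfs,
                           atol=1e-10, equal_nan=True)

    def test_circular_shift_of_tapered_frame_invariant(self, rng):
        epoch = rng.normal(size=(6, 256))
        taper = signal.get_window("hann", 256, fftbins=True)
        tapered = epoch * taper
        shifted = np.roll(tapered, 17, axis=1)
        a = gfs_spectrum(tapered, 256.0, window="boxcar")
        b = gfs_spectrum(shifted, 256.0, window="boxcar")
        assert np.allclose(a.gfs, b.gfs, atol=1e-9, equal_nan=True)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            gfs_spectrum(rng.normal(size=(1, 256)), 256.0)

    def test_zero_power_bins_undefined_not_zero(self):
        epoch = np.zeros((4, 256))
        spec = gfs_spectrum(epoch, 256.0)
        assert np.all(np.isnan(spec.gfs))


class TestBandAverage:
    def test_constant_band_returns_constant(self, rng):
        spec = gfs_spectrum(rng.normal(size=(4, 512)), 256.0)
        spec.gfs[:] = 0.37
        assert band_average(spec) == pytest.approx(0.37)

    def test_inclusive_edges_cover_23_bins_at_half_hz(self, rng):
        # 2-s epochs -> 0.5 Hz bins -> 14.0, 14.5, ..., 25.0
        spec = gfs_spectrum(rng.normal(size=(4, 512)), 256.0)
        spec.gfs[:] = 0.0
        mask = (spec.frequencies >= 14.0) & (spec.frequencies <= 25.0)
        assert mask.sum() == 23
        spec.gfs[mask] = 1.0
        assert band_average(spec) == pytest.approx(1.0)

    def test_band_without_bins_rejected(self, rng):
        spec = gfs_spectrum(rng.normal(size=(4, 512)), 256.0)
        with pytest.raises(ConfigurationError):
            band_average(spec, 14.1, 14.2)


class TestSubjectSeries:
    def test_rank_one_limit(self):
        script = StimulusScript(duration=120.0)
        cfg = GroupConfig(seed=2, baseline_sync=1.0, noise_sd=0.0)
        series = subject_gfs_series(simulate_eeg(script, cfg, 0))
        assert np.all(series.values >= 0.95)

    def test_desync_event_lowers_series(self):
        script = StimulusScript(
            duration=120.0, events=(StimulusEvent(30.0, 40.0, "desync", 0.8),)
        )
        ins, outs = [], []
        for seed in range(10):
            cfg = GroupConfig(seed=seed)
            s = subject_gfs_series(simulate_eeg(script, cfg, 0))
            inside = (s.times >= 31) & (s.times <= 39)
            outside = (s.times <= 25) | (s.times >= 45)
            ins.append(np.mean(s.values[inside]))
            outs.append(np.mean(s.values[outside]))
        assert np.mean(outs) - np.mean(ins) > 0.05
        assert sum(i < o for i, o in zip(ins, outs)) >= 9

    def test_channel_exclusion_stays_finite(self, script):
        cfg = GroupConfig(seed=3)
        rec = simulate_eeg(script, cfg, 0)
        gfs_cfg = GFSConfig(exclude_channels=("T8", "C3"))
        series = subject_gfs_series(rec, gfs_cfg)
        assert np.all(np.isfinite(series.values))
        assert len(series) == len(subject_gfs_series(rec))

    def test_epoch_center_timestamps(self, script):
        cfg = GroupConfig(seed=3)
        series = subject_gfs_series(simulate_eeg(script, cfg, 0))
        assert series.times[0] == pytest.approx(1.0)
        assert series.dt == pytest.approx(1.0)


class TestBandPSDSeries:
    def test_in_band_tone_gives_flat_series(self):
        t = np.arange(30 * 256) / 256.0
        x = np.sin(2 * np.pi * 20 * t)
        rec = _eeg(np.vstack([x, np.zeros_like(x)]))
        s = band_psd_series(rec, "ch0", 14.0, 25.0)
        core = s.values[3:-3]
        assert np.std(core) / np.mean(core) < 0.01

    def test_power_scales_quadratically(self):
        t = np.arange(30 * 256) / 256.0
        x = np.sin(2 * np.pi * 20 * t)
        rec1 = _eeg(np.vstack([x, np.zeros_like(x)]))
        rec2 = _eeg(np.vstack([2 * x, np.zeros_like(x)]))
        s1 = band_psd_series(rec1, "ch0", 14.0, 25.0)
        s2 = band_psd_series(rec2, "ch0", 14.0, 25.0)
        assert np.median(s2.values[3:-3] / s1.values[3:-3]) == pytest.approx(4.0, rel=1e-6)

    def test_matches_periodogram_oracle(self, rng):
        x = rng.normal(size=20 * 256)
        rec = _eeg(np.vstack([x, rng.normal(size=len(x))]))
        cfg = GFSConfig(bandpass_low=1.0, bandpass_high=55.0)
        s = band_psd_series(rec, "ch0", 14.0, 25.0, cfg)
        # recompute epoch 5 by the direct formula on identically preprocessed data
        pre = bandpass(remove_dc(rec), 1.0, 55.0)
        seg = pre.samples[0, 5 * 256:5 * 256 + 512]
        assert s.values[5] == pytest.approx(band_psd_direct(seg, 256.0, 14.0, 25.0), abs=1e-8)

    def test_unknown_channel_rejected(self, rng):
        rec = _eeg(rng.normal(size=(2, 1024)))
        with pytest.raises(ConfigurationError):
            band_psd_series(rec, "Oz", 14.0, 25.0)
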