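"""Preprocessing stage contracts: QC, optical density, despiking, filtering,
and the Beer--Lambert inversion, each against an independent oracle."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from nirsdual.preprocess import (FilterDesign, PreprocessConfig, QCThresholds,
                                 WaveletConfig, bandpass, intensity_to_od,
                                 mbll, preprocess, reject_channels, wavelet_mar)
from nirsdual.probe import ExtinctionTable, default_layout
from nirsdual.recording import RawRecording
from nirsdual.sim import forward_mbll, simulate_recording
from nirsdual.sim.forward import DEFAULT_I0


def _fixture_recording() -> RawRecording:
    """18 channels: #1 saturated (one sample at 4501), #5 high dark current,
    #9 correlated with ambient, rest clean."""
    rng = np.random.default_rng(0)
    layout = default_layout()
    n = 600
    t = np.arange(n) / 10.0
    base = 2000 + 30 * rng.standard_normal((18, n))
    i750 = base.copy()
    i830 = base + 200
    ambient = 400 + 5 * rng.standard_normal((18, n))
    dark = np.full(18, 50.0)
    i750[0, 300] = 4501.0
    dark[4] = 250.0
    i750[8] = ambient[8] * 6 + 10 * rng.standard_normal(n)  # r ~ 0.95
    return RawRecording(subject="X", session="E1", fs=10.0, t=t,
                        i750=i750, i830=i830, ambient=ambient,
                        dark_current=dark, layout=layout)


class TestRejectChannels:
    def test_three_planted_failures_flagged_with_reasons(self):
        qc = reject_channels(_fixture_recording())
        assert qc.n_retained == 15
        assert qc.reasons[0] == "saturated"
        assert qc.reasons[4] == "dark_current"
        assert qc.reasons[8] == "ambient_corr"
        assert all(r == "" for i, r in enumerate(qc.reasons) if i not in (0, 4, 8))

    def test_single_sample_above_ceiling_rejects(self):
        rec = _fixture_recording()
        qc = reject_channels(rec, QCThresholds(saturation=4500.5))
        assert qc.reasons[0] == "saturated"
        qc2 = reject_channels(rec, QCThresholds(saturation=4501.0))
        assert qc2.reasons[0] != "saturated"   # 4501 is not > 4501

    def test_tightening_thresholds_never_grows_retained_set(self):
        rec = _fixture_recording()
        base = reject_channels(rec, QCThresholds())
        for th in (QCThresholds(saturation=3000),
                   QCThresholds(dark_current=40),
                   QCThresholds(ambient_corr=0.05)):
            tight = reject_channels(rec, th)
            assert set(np.flatnonzero(tight.retained)) <= set(np.flatnonzero(base.retained))

    def test_constant_series_skips_correlation(self, caplog):
        rec = _fixture_recording()
        rec.ambient[:] = 400.0
        qc = reject_channels(rec)
        assert qc.reasons[8] == ""  # criterion not triggered on constant ambient


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(np.full(100, 1500.0))
        assert np.allclose(od, 0.0)

    def test_half_intensity_sample_is_log10_two(self):
        x = np.full(1000, 1000.0)
        x[500] = 500.0
        od = intensity_to_od(x)
        # I0 is the temporal mean (slightly below 1000 due to the dip)
        i0 = x.mean()
        assert od[500] == pytest.approx(np.log10(i0 / 500.0), abs=1e-12)
        assert od[500] == pytest.approx(np.log10(2.0), abs=2e-3)

    def test_ambient_only_channel_raises(self):
        amb = np.full(100, 400.0)
        with pytest.raises(ValueError):
            intensity_to_od(amb, ambient=amb)

    def test_nonpositive_samples_interpolated(self):
        x = np.full(100, 1000.0)
        x[10] = 0.0
        od = intensity_to_od(x, ambient=np.full(100, 400.0))
        assert np.all(np.isfinite(od))

    def test_first30s_baseline_config(self):
        x = np.concatenate([np.full(300, 1000.0), np.full(300, 500.0)])
        od = intensity_to_od(x, baseline="first30s", fs=10.0)
        assert od[0] == pytest.approx(0.0)
        assert od[-1] == pytest.approx(np.log10(2.0))


class TestWaveletMAR:
    def test_zero_in_zero_out(self):
        assert np.allclose(wavelet_mar(np.zeros(1024)), 0.0)

    def test_spike_suppressed_sinusoid_preserved(self):
        fs = 10.0
        t = np.arange(4096) / fs
        clean = 0.1 * np.sin(2 * np.pi * 0.05 * t)
        spiky = clean.copy()
        i0 = 2000
        spike_amp = 10 * np.std(clean)
        spiky[i0:i0 + 5] += spike_amp
        out = wavelet_mar(spiky)
        residual_peak = np.max(np.abs(out[i0:i0 + 5] - clean[i0:i0 + 5]))
        assert residual_peak < 0.2 * spike_amp          # >= 80% suppression
        rms_clean = np.sqrt(np.mean(clean**2))
        rms_out = np.sqrt(np.mean((out[:i0 - 50])**2))  # away from the spike
        assert abs(rms_out - rms_clean) / rms_clean < 0.10

    def test_smooth_signal_passes_through(self):
        t = np.arange(2048) / 10.0
        x = np.sin(2 * np.pi * 0.02 * t)
        out = wavelet_mar(x)
        assert np.sqrt(np.mean((out - x)**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_short_series_passthrough_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            out = wavelet_mar(x, WaveletConfig(level=5))
        assert np.array_equal(out, x)


class TestBandpass:
    def test_dc_removed(self):
        y = bandpass(np.ones(7700), 10.0)
        assert np.max(np.abs(y)) < 10 ** (-20 / 20)   # >= 20 dB down

    def test_passband_sinusoid_within_1db(self):
        t = np.arange(7700) / 10.0
        y = bandpass(np.sin(2 * np.pi * 0.03 * t), 10.0)
        amp = np.sqrt(2) * np.std(y[1500:-1500])
        assert 10 ** (-1 / 20) < amp < 10 ** (1 / 20)

    def test_respiration_band_suppressed(self):
        t = np.arange(7700) / 10.0
        y = bandpass(np.sin(2 * np.pi * 0.25 * t), 10.0)
        assert np.sqrt(2) * np.std(y[1500:-1500]) <= 0.1

    def test_too_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="samples"):
            bandpass(np.zeros(800), 10.0)

    def test_matches_filtfilt_reference(self):
        """The FFT zero-phase implementation must agree with the textbook
        forward-backward application of the same taps."""
        d = FilterDesign()
        hp, lp = d.taps(10.0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(7700)
        ref = signal.filtfilt(hp, [1.0], x, padlen=4203)
        ref = signal.filtfilt(lp, [1.0], ref, padlen=4203)
        assert np.max(np.abs(ref - bandpass(x, 10.0))) < 1e-10 * np.std(ref)

    def test_two_dimensional_matches_per_row(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 5000))
        y2 = bandpass(x, 10.0)
        for j in range(3):
            assert np.allclose(y2[j], bandpass(x[j], 10.0))

    def test_idempotent_on_passband_signal(self):
        t = np.arange(7700) / 10.0
        x = np.sin(2 * np.pi * 0.03 * t)
        once = bandpass(x, 10.0)
        twice = bandpass(once, 10.0)
        core = slice(1500, -1500)
        assert np.sqrt(np.mean((twice[core] - once[core])**2)) \
            < 0.06 * np.sqrt(np.mean(once[core]**2))


class TestMBLL:
    def test_zero_od_gives_zero_concentration(self):
        ch = default_layout().channel(1)
        hbo, hbr = mbll(np.zeros(10), np.zeros(10), ch)
        assert np.all(hbo == 0) and np.all(hbr == 0)

    def test_hand_solved_two_by_two(self):
        """With eps rows [[0.5179, 1.4066], [0.9740, 0.6930]], d*DPF = 15 cm,
        OD = (0.03, 0.06): solving by hand gives (mM)
        [dHbO, dHbR] = E^-1 @ [0.002, 0.004]."""
        ch = default_layout().channel(1)           # 2.5 cm, DPF 6 -> d*DPF = 15
        tab = ExtinctionTable()
        E = np.array([[0.5179, 1.4066], [0.9740, 0.6930]])
        expected_mM = np.linalg.solve(E, np.array([0.03, 0.06]) / 15.0)
        hbo, hbr = mbll(np.array([0.03]), np.array([0.06]), ch, tab)
        assert hbo[0] == pytest.approx(expected_mM[0] * 1000, rel=1e-12)
        assert hbr[0] == pytest.approx(expected_mM[1] * 1000, rel=1e-12)

    def test_forward_inverse_round_trip_exact(self):
        rng = np.random.default_rng(3)
        layout = default_layout()
        hbo = rng.normal(0, 1, (18, 200))
        hbr = rng.normal(0, 0.3, (18, 200))
        raw = forward_mbll(hbo, hbr, layout)
        for j, ch in enumerate(layout.channels):
            od750 = -np.log10(raw[750][j] / DEFAULT_I0[750])
            od830 = -np.log10(raw[830][j] / DEFAULT_I0[830])
            got_hbo, got_hbr = mbll(od750, od830, ch)
            assert np.allclose(got_hbo, hbo[j], atol=1e-6)
            assert np.allclose(got_hbr, hbr[j], atol=1e-6)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        ch = default_layout().channel(3)
        od750, od830 = rng.standard_normal(50) * 0.01, rng.standard_normal(50) * 0.01
        h1, r1 = mbll(od750, od830, ch)
        h3, r3 = mbll(3 * od750, 3 * od830, ch)
        assert np.allclose(h3, 3 * h1) and np.allclose(r3, 3 * r1)

    def test_singular_coeffs_error(self):
        ch = default_layout().channel(1)
        with pytest.raises(ValueError):
            # construction itself rejects a singular table
            ExtinctionTable(eps_hbo={750: 1.0, 830: 2.0}, eps_hbr={750: 0.5, 830: 1.0})
        del ch


def test_end_to_end_noise_free_recovery(tiny_cfg, noisefree_recording):
    """Preprocessing applied to the forward model's output recovers the
    band-passed ground truth on every long channel."""
    rec, truth = noisefree_recording
    hemo = preprocess(rec)
    assert hemo.qc.n_retained == 18
    assert hemo.provenance == ["reject_channels", "intensity_to_od",
                               "wavelet_mar", "bandpass", "mbll"]
    for j in range(16):
        gt = bandpass(truth.hbo[j], tiny_cfg.fs)
        out = hemo.hbo[j]
        assert np.corrcoef(gt, out)[0, 1] > 0.99
        amp = np.dot(out, gt) / np.dot(gt, gt)
        assert abs(amp - 1.0) < 0.05


def test_rejected_channels_are_nan(noisy_recording):
    rec, _ = noisy_recording
    bad = dataclasses.replace(rec)
    bad.i750 = rec.i750.copy()
    bad.i750[2, 100] = 5000.0
    hemo = preprocess(bad)
    assert not hemo.qc.retained[2]
    assert np.isnan(hemo.hbo[2]).all()
    assert np.isfinite(hemo.hbo[0]).all()
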