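"""R-peak detection, tachogram repair, resampling, detrending, Burg powers."""

import numpy as np
import pytest

from sleepcoupling.hrv import (
    RRISeries,
    burg_hrv_power,
    correct_rri,
    detect_r_peaks,
    detrend_rri,
    resample_rri,
)
from sleepcoupling.signal_io import RawSignal
from sleepcoupling.synthetic import SimConfig, gen_ecg, gen_hypnogram, gen_modulator


def _match(true_t, det_t, tol=0.02):
    """(sensitivity, precision) of detected peak times vs ground truth."""
    if det_t.size == 0:
        return 0.0, 0.0
    d = np.abs(true_t[:, None] - det_t[None, :])
    sens = np.mean(d.min(axis=1) <= tol)
    prec = np.mean(d.min(axis=0) <= tol)
    return sens, prec


@pytest.fixture(scope="module")
def clean_ecg():
    cfg = SimConfig(duration_s=300.0, seed=21, a_lf=0.0, a_hf=0.0, rr_noise=0.0,
                    ecg_snr_db=20.0, mean_rr_s=1.0)
    hyp = gen_hypnogram(cfg)
    mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
    return gen_ecg(cfg, hyp, mod)


class TestDetectRPeaks:
    def test_sixty_bpm_all_peaks_within_tolerance(self, clean_ecg):
        ecg, true_t = clean_ecg
        det = detect_r_peaks(ecg)
        sens, prec = _match(true_t, det)
        assert sens == 1.0 and prec == 1.0

    def test_zero_signal_returns_empty(self):
        sig = RawSignal(np.zeros(500 * 20) + 1.0, rate=500.0)
        assert detect_r_peaks(sig).size == 0

    def test_amplitude_scale_invariance(self, clean_ecg):
        ecg, _ = clean_ecg
        det1 = detect_r_peaks(ecg)
        det2 = detect_r_peaks(RawSignal(5.0 * ecg.samples, rate=ecg.rate))
        assert np.array_equal(det1, det2)

    def test_low_rate_raises(self):
        with pytest.raises(ValueError):
            detect_r_peaks(RawSignal(np.random.default_rng(0).random(2000), rate=100.0))


class TestCorrectRri:
    def test_single_outlier_replaced_by_local_mean(self):
        t = np.cumsum(np.concatenate([[0.0], np.full(40, 0.8)]))
        t[21:] += 1.2  # one 2.0 s interval in a 0.8 s train
        rri = RRISeries(peak_times_s=t)
        out = correct_rri(rri)
        assert np.sum(out.quality_flags == "replaced") == 1
        assert out.intervals_s[20] == pytest.approx(0.8, abs=0.06)

    def test_zero_variance_window_is_kept(self):
        t = np.cumsum(np.concatenate([[0.0], np.full(30, 0.8)]))
        out = correct_rri(RRISeries(peak_times_s=t))
        assert np.all(out.quality_flags == "kept")
        assert np.allclose(out.intervals_s, 0.8)

    def test_identity_when_no_point_exceeds_threshold(self, rng):
        t = np.cumsum(np.concatenate([[0.0], 0.8 + 0.01 * rng.standard_normal(50)]))
        rri = RRISeries(peak_times_s=t)
        out = correct_rri(rri)
        assert np.array_equal(out.intervals_s, rri.intervals_s)

    def test_too_few_intervals_raises(self):
        with pytest.raises(ValueError):
            correct_rri(RRISeries(peak_times_s=np.array([0.0, 0.8, 1.6])))

    def test_preserves_interval_count(self, rng):
        t = np.cumsum(np.concatenate([[0.0], 0.8 + 0.05 * rng.standard_normal(100)]))
        rri = RRISeries(peak_times_s=t)
        assert correct_rri(rri).intervals_s.size == rri.intervals_s.size


class TestResampleRri:
    def test_constant_series_resamples_flat(self):
        t = np.cumsum(np.concatenate([[0.0], np.full(50, 0.8)]))
        res = resample_rri(RRISeries(peak_times_s=t))
        assert np.allclose(res.values, 0.8, atol=1e-9)

    def test_grid_spacing_exact(self):
        t = np.cumsum(np.concatenate([[0.0], np.full(50, 0.8)]))
        res = resample_rri(RRISeries(peak_times_s=t))
        assert np.allclose(np.diff(res.times()), 0.125)

    def test_modulation_frequency_survives(self):
        times = [0.0]
        while times[-1] < 200:
            times.append(times[-1] + 0.8 * (1 + 0.1 * np.sin(2 * np.pi * 0.1 * times[-1])))
        res = resample_rri(RRISeries(peak_times_s=np.array(times)))
        spec = np.abs(np.fft.rfft(res.values - res.values.mean()))
        f = np.fft.rfftfreq(res.values.size, 1 / 8.0)
        assert abs(f[np.argmax(spec)] - 0.1) < 0.01

    def test_too_few_peaks_raises(self):
        with pytest.raises(ValueError):
            resample_rri(RRISeries(peak_times_s=np.array([1.0])))


class TestDetrendRri:
    def test_removes_drift_keeps_oscillation(self):
        from sleepcoupling.hrv import ResampledRRI

        t = np.arange(0, 600, 0.125)
        osc = 0.05 * np.sin(2 * np.pi * 0.1 * t)
        drift = 0.8 + 0.0005 * t
        out = detrend_rri(ResampledRRI(values=osc + drift, rate=8.0, start_s=0.0))
        assert np.corrcoef(out.values, osc)[0, 1] > 0.99

    def test_constant_input_maps_to_zero(self):
        from sleepcoupling.hrv import ResampledRRI

        out = detrend_rri(ResampledRRI(values=np.full(8192, 0.8), rate=8.0, start_s=0.0))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_idempotent_up_to_edge_effects(self, rng):
        from sleepcoupling.hrv import ResampledRRI

        x = 0.8 + 0.05 * np.sin(2 * np.pi * 0.05 * np.arange(0, 800, 0.125))
        once = detrend_rri(ResampledRRI(values=x, rate=8.0, start_s=0.0))
        twice = detrend_rri(once)
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert abs(rms(twice.values) - rms(once.values)) < 0.01 * rms(once.values)


class TestBurgPower:
    def _series(self, f_mod):
        times = [0.0]
        while times[-1] < 700:
            times.append(times[-1] + 0.9 * (1 + 0.05 * np.sin(2 * np.pi * f_mod * times[-1])))
        res = detrend_rri(resample_rri(RRISeries(peak_times_s=np.array(times))))
        return burg_hrv_power(res)

    def test_lf_modulation_localised(self):
        by = {s.band: s.values for s in self._series(0.1)}
        frac = np.nanmean(by["LF"] / (by["LF"] + by["HF"]))
        assert frac > 0.8

    def test_hf_modulation_localised(self):
        by = {s.band: s.values for s in self._series(0.3)}
        frac = np.nanmean(by["HF"] / (by["LF"] + by["HF"]))
        assert frac > 0.8

    def test_relative_powers_sum_to_one(self):
        series = self._series(0.1)
        by = {s.band: s.values for s in series}
        total = by["VLF"] + by["LF"] + by["HF"]
        assert np.allclose(total[np.isfinite(total)], 1.0, atol=1e-6)

    def test_window_centre_timestamps(self):
        s = self._series(0.1)[0]
        assert s.time_s[0] >= 150.0
        assert np.all(np.diff(s.time_s) == pytest.approx(1.0))
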