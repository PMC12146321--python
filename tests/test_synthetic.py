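"""Synthetic night generator: determinism, stage structure, injected truth."""

import numpy as np
import pytest

from sleepcoupling.signal_io import group_stage
from sleepcoupling.synthetic import (
    SimConfig,
    gen_activity,
    gen_bs,
    gen_ecg,
    gen_eeg,
    gen_hypnogram,
    gen_modulator,
    standard_schedule,
)

ALL_STAGES = ("Awake", "LS", "DS", "REM")


def _cfg(**kw):
    kw.setdefault("duration_s", 600.0)
    kw.setdefault("seed", 5)
    return SimConfig(**kw)


class TestHypnogram:
    def test_schedule_counting(self):
        cfg = _cfg(stage_schedule=[("W", 300.0), ("N2", 600.0)], duration_s=900.0)
        hyp = gen_hypnogram(cfg)
        assert len(hyp.stages) == 30
        assert hyp.stages[:10] == ["W"] * 10 and hyp.stages[10:] == ["N2"] * 20

    def test_empty_schedule_raises(self):
        with pytest.raises(ValueError):
            gen_hypnogram(_cfg(stage_schedule=[]))

    def test_non_multiple_duration_rounded_down_with_warning(self):
        cfg = _cfg(stage_schedule=[("W", 45.0), ("N2", 60.0)])
        with pytest.warns(UserWarning):
            hyp = gen_hypnogram(cfg)
        assert len(hyp.stages) == 3

    def test_default_template_stage_fractions(self):
        cfg = _cfg(duration_s=8 * 3600.0)
        hyp = gen_hypnogram(cfg)
        grouped = hyp.grouped
        frac = {s: grouped.count(s) / len(grouped) for s in ALL_STAGES}
        # hourly template: W 900, LS 900, DS 900, REM 900 seconds
        for s in ALL_STAGES:
            assert frac[s] == pytest.approx(0.25, abs=0.05)


class TestModulator:
    def test_deterministic_under_seed(self):
        a = gen_modulator(600.0, seed=9)
        b = gen_modulator(600.0, seed=9)
        assert np.array_equal(a.samples, b.samples)
        c = gen_modulator(600.0, seed=10)
        assert not np.array_equal(a.samples, c.samples)

    def test_unit_variance(self):
        m = gen_modulator(8 * 3600.0, seed=1)
        assert np.var(m.samples) == pytest.approx(1.0, abs=0.1)

    def test_band_limited(self):
        band = (0.001, 0.003)
        m = gen_modulator(8 * 3600.0, band=band, seed=2)
        spec = np.abs(np.fft.rfft(m.samples)) ** 2
        f = np.fft.rfftfreq(m.samples.size, 1.0)
        inside = spec[(f >= band[0] - 1e-6) & (f <= band[1] + 1e-6)].sum()
        assert inside / spec.sum() > 0.95

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            gen_modulator(100.0, seed=0)


class TestEeg:
    def test_uncoupled_envelope_independent_of_modulator(self):
        cfg = _cfg(duration_s=1200.0, coupling_per_stage={s: 0.0 for s in ALL_STAGES},
                   stage_schedule=[("N2", 1200.0)])
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        eeg = gen_eeg(cfg, hyp, mod)
        # 1-s RMS envelope vs modulator
        env = eeg.samples[: 1200 * 500].reshape(1200, 500).std(axis=1)
        r = np.corrcoef(env, mod.samples[:1200])[0, 1]
        assert abs(r) < 0.1

    def test_delta_dominates_deep_sleep(self):
        cfg = _cfg(duration_s=1200.0, stage_schedule=[("W", 600.0), ("N3", 600.0)])
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        from sleepcoupling.eeg import eeg_band_power

        delta = [s for s in eeg_band_power(gen_eeg(cfg, hyp, mod)) if s.band == "delta"][0]
        wake = delta.values[delta.time_s < 590]
        deep = delta.values[delta.time_s >= 610]
        assert np.median(deep) > np.median(wake)

    def test_coupled_delta_power_tracks_modulator(self):
        cfg = _cfg(duration_s=1800.0, coupling_per_stage={s: 1.0 for s in ALL_STAGES},
                   system_gain={"eeg": 1.0, "ecg": 1.0, "bs": 1.0},
                   stage_schedule=[("N2", 1800.0)])
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        from sleepcoupling.eeg import eeg_band_power

        delta = [s for s in eeg_band_power(gen_eeg(cfg, hyp, mod)) if s.band == "delta"][0]
        m = np.interp(delta.time_s, np.arange(mod.samples.size), mod.samples)
        assert np.corrcoef(delta.values, m)[0, 1] > 0.6


class TestEcg:
    def test_unmodulated_rr_is_constant(self):
        cfg = _cfg(a_lf=0.0, a_hf=0.0, rr_noise=0.0)
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        _, peaks = gen_ecg(cfg, hyp, mod)
        assert np.allclose(np.diff(peaks), cfg.mean_rr_s, atol=1.0 / cfg.ecg_rate)

    def test_peak_count_matches_mean_rate(self):
        cfg = _cfg()
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        _, peaks = gen_ecg(cfg, hyp, mod)
        assert peaks.size == pytest.approx(cfg.duration_s / cfg.mean_rr_s, abs=8)

    def test_lf_only_modulation_lands_in_lf_band(self):
        from sleepcoupling.hrv import RRISeries, burg_hrv_power, detrend_rri, resample_rri

        cfg = _cfg(duration_s=900.0, a_lf=0.05, a_hf=0.0, rr_noise=0.0,
                   coupling_per_stage={s: 0.0 for s in ALL_STAGES})
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        _, peaks = gen_ecg(cfg, hyp, mod)
        series = burg_hrv_power(detrend_rri(resample_rri(RRISeries(peak_times_s=peaks))))
        by = {s.band: s.values for s in series}
        assert np.nanmean(by["LF"] / (by["LF"] + by["HF"])) > 0.8

    def test_extreme_modulation_rejected(self):
        cfg = _cfg(a_lf=0.9, rr_noise=0.0)
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        with pytest.raises(ValueError):
            gen_ecg(cfg, hyp, mod)


class TestBs:
    def test_zero_rate_produces_no_bursts(self):
        cfg = _cfg(bs_burst_rate_hz={s: 0.0 for s in ALL_STAGES})
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        audio, bursts = gen_bs(cfg, hyp, mod)
        assert bursts.size == 0
        # only leakage + sensor noise remains
        assert audio.bs.samples.std() < 5 * (cfg.bs_leak * cfg.ns_rms + cfg.bs_noise_rms)

    def test_same_seed_reproduces_audio(self):
        cfg = _cfg()
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        a1, b1 = gen_bs(cfg, hyp, mod)
        a2, b2 = gen_bs(cfg, hyp, mod)
        assert np.array_equal(a1.bs.samples, a2.bs.samples)
        assert np.array_equal(b1, b2)

    def test_burst_counts_track_modulator_at_full_coupling(self):
        cfg = _cfg(duration_s=3600.0, coupling_per_stage={s: 1.0 for s in ALL_STAGES},
                   stage_schedule=[("N2", 3600.0)])
        hyp = gen_hypnogram(cfg)
        mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
        _, bursts = gen_bs(cfg, hyp, mod)
        counts = np.histogram(bursts, bins=np.arange(0, 3601, 300))[0]
        m5 = mod.samples[:3600].reshape(12, 300).mean(axis=1)
        assert np.corrcoef(counts, m5)[0, 1] > 0.5


class TestActivity:
    def test_zero_rate_stays_below_threshold(self):
        cfg = _cfg(movement_rate_per_hour={s: 0.0 for s in ALL_STAGES})
        act, intervals = gen_activity(cfg, gen_hypnogram(cfg))
        assert intervals == [] and np.all(act.values < 0.2)

    def test_every_interval_contains_excursion(self):
        cfg = _cfg(duration_s=3600.0, movement_rate_per_hour={s: 20.0 for s in ALL_STAGES})
        act, intervals = gen_activity(cfg, gen_hypnogram(cfg))
        assert intervals
        t = act.times()
        for a, b in intervals:
            assert np.any(act.values[(t >= a) & (t < b)] > 0.2)

    def test_exclusion_recovers_injected_intervals(self):
        from sleepcoupling.pipeline import exclude_movement, segment_stage_windows

        cfg = _cfg(duration_s=5400.0, movement_rate_per_hour={s: 8.0 for s in ALL_STAGES})
        hyp = gen_hypnogram(cfg)
        act, intervals = gen_activity(cfg, hyp)
        windows = segment_stage_windows(hyp, cfg.duration_s)
        exclude_movement(windows, act)
        excluded = [(w.start_s, w.end_s) for w in windows if w.excluded and w.reason == "movement"]
        hit = sum(
            any(a < we and b > ws for ws, we in excluded) for a, b in intervals
        )
        # windowed nights drop sub-300-s remainders, so a few intervals fall
        # outside any window; of those covered, >= 95 % must trigger exclusion
        covered = [
            (a, b)
            for a, b in intervals
            if any(a < w.end_s and b > w.start_s for w in windows)
        ]
        hit_cov = sum(
            any(a < we and b > ws for ws, we in excluded) for a, b in covered
        )
        assert covered and hit_cov / len(covered) >= 0.95


class TestCouplingMonotonicity:
    def test_extracted_dependence_increases_with_c(self):
        """Raising c never weakens the modulator correlation (fixed seed)."""
        from sleepcoupling.eeg import eeg_band_power

        cors = []
        for c in (0.0, 0.5, 1.0):
            cfg = _cfg(duration_s=1800.0, coupling_per_stage={s: c for s in ALL_STAGES},
                       system_gain={"eeg": 1.0, "ecg": 1.0, "bs": 1.0},
                       stage_schedule=[("N2", 1800.0)], seed=5)
            hyp = gen_hypnogram(cfg)
            mod = gen_modulator(cfg.duration_s, cfg.modulator_band, cfg.seed)
            delta = [s for s in eeg_band_power(gen_eeg(cfg, hyp, mod)) if s.band == "delta"][0]
            m = np.interp(delta.time_s, np.arange(mod.samples.size), mod.samples)
            cors.append(np.corrcoef(delta.values, m)[0, 1])
        assert cors[0] < cors[1] < cors[2]


def test_standard_schedule_runs_are_window_aligned():
    sched = standard_schedule(5400.0)
    assert sum(d for _, d in sched) == 5400
    assert all(d % 30 == 0 for _, d in sched)
    assert {group_stage(s) for s, _ in sched} == set(ALL_STAGES)
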