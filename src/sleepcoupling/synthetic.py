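"""Synthetic polysomnography night with known cross-system coupling.

Generates a full "night" — stage-structured EEG, an ECG with LF/HF-modulated
RR intervals, dual-channel bowel-sound audio, a hypnogram and a body-movement
activity trace — driven by one shared slow modulator.  The modulator
multiplies the EEG band amplitudes, the LF amplitude of the RR process and
the bowel-sound burst statistics, with a per-stage coupling coefficient
``c in [0, 1]``; this common drive is what makes MIC-detectable dependence
between the three systems' band-power series, and every injected event
(R peaks, bursts, movements) is returned as ground truth for detector tests.

The modulator occupies 0.001-0.003 Hz — entirely below the first zero of
the 300-s HRV estimation window's sinc response at 1/300 Hz, so the HRV
series carries a sign-consistent (if attenuated) copy of the drive; faster
bands are annihilated or sign-scrambled by that window (see the methods
note).  Per-system gains allow asymmetric injection — by default the brain
responds at reduced gain, so heart-gut coupling is injected stronger than
brain-gut coupling.

All generators are deterministic functions of the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .signal_io import ActivitySeries, DualChannelAudio, Hypnogram, RawSignal

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticNight",
    "standard_schedule",
    "gen_hypnogram",
    "gen_modulator",
    "gen_eeg",
    "gen_ecg",
    "gen_bs",
    "gen_activity",
    "gen_night",
]

_STAGES = ("Awake", "LS", "DS", "REM")

# One-hour schedule template (AASM labels, seconds); every run is a multiple
# of 300 s so 5-min windows tile stage runs without boundary loss.
_HOUR_PATTERN: List[Tuple[str, int]] = [
    ("W", 600),
    ("N1", 300),
    ("N2", 300),
    ("N3", 600),
    ("R", 600),
    ("W", 300),
    ("N2", 300),
    ("N3", 300),
    ("R", 300),
]


def standard_schedule(duration_s: float) -> List[Tuple[str, int]]:
    """Cyclic wake -> light -> deep -> REM schedule truncated to ``duration_s``."""
    out: List[Tuple[str, int]] = []
    t = 0
    while t < duration_s:
        for stage, dur in _HOUR_PATTERN:
            d = int(min(dur, duration_s - t))
            if d <= 0:
                break
            out.append((stage, d))
            t += d
    return out


@dataclass
class SimConfig:
    """Study conditions for one synthetic night.

    ``coupling_per_stage`` is the per-stage coupling coefficient of every
    system to the shared modulator; ``system_gain`` scales it per system
    (brain at half gain by default so heart-gut coupling is injected stronger
    than brain-gut coupling).
    """

    duration_s: float = 5400.0
    seed: int = 0
    stage_schedule: Optional[List[Tuple[str, float]]] = None
    coupling_per_stage: Dict[str, float] = field(
        default_factory=lambda: {"Awake": 0.9, "LS": 0.6, "DS": 0.3, "REM": 0.7}
    )
    system_gain: Dict[str, float] = field(
        default_factory=lambda: {"eeg": 0.35, "ecg": 1.0, "bs": 1.0}
    )
    eeg_band_amplitudes: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "Awake": {"delta": 10.0, "theta": 8.0, "alpha": 15.0, "beta": 10.0},
            "LS": {"delta": 20.0, "theta": 12.0, "alpha": 8.0, "beta": 5.0},
            "DS": {"delta": 40.0, "theta": 12.0, "alpha": 5.0, "beta": 3.0},
            "REM": {"delta": 12.0, "theta": 10.0, "alpha": 7.0, "beta": 6.0},
        }
    )
    eeg_noise_uv: float = 2.0
    mean_rr_s: float = 0.9
    lf_hz: float = 0.1
    hf_hz: float = 0.25
    a_lf: float = 0.07
    a_hf: float = 0.035
    rr_noise: float = 0.004
    ecg_snr_db: float = 20.0
    bs_burst_rate_hz: Dict[str, float] = field(
        default_factory=lambda: {"Awake": 0.30, "LS": 0.25, "DS": 0.20, "REM": 0.25}
    )
    bs_leak: float = 0.4
    bs_noise_rms: float = 0.004
    ns_rms: float = 0.05
    movement_rate_per_hour: Dict[str, float] = field(
        default_factory=lambda: {"Awake": 5.0, "LS": 1.0, "DS": 0.3, "REM": 0.6}
    )
    modulator_band: Tuple[float, float] = (0.001, 0.003)
    eeg_rate: float = 500.0
    ecg_rate: float = 500.0
    bs_rate: float = 8000.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.3 < self.mean_rr_s < 2.0:
            raise ValueError("mean_rr_s must lie in (0.3, 2.0) s")
        for k, v in self.coupling_per_stage.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coupling for {k} must lie in [0, 1]")
        if self.stage_schedule is None:
            self.stage_schedule = standard_schedule(self.duration_s)


@dataclass
class GroundTruth:
    """Injected events and drivers: the oracle for every detector test."""

    r_peak_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    bs_burst_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    modulator: Optional[RawSignal] = None
    movement_intervals: List[Tuple[float, float]] = field(default_factory=list)
    coupling_per_stage: Dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticNight:
    """Bundle of every generated channel plus ground truth."""

    config: SimConfig
    hypnogram: Hypnogram
    eeg: RawSignal
    ecg: RawSignal
    audio: DualChannelAudio
    activity: ActivitySeries
    truth: GroundTruth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _coupling_modulation(u: np.ndarray) -> np.ndarray:
    """Clipped linear map g of the modulator; 1 + c*g stays positive."""
    return np.clip(0.6 * u, -0.95, 0.95)


def _stage_per_second(hyp: Hypnogram, duration_s: float) -> List[str]:
    sec = []
    g = hyp.grouped
    for t in range(int(duration_s)):
        i = min(t // hyp.epoch_seconds, len(g) - 1)
        sec.append(g[i])
    return sec


def gen_hypnogram(config: SimConfig) -> Hypnogram:
    """Concatenate the 30-s epochs of the configured stage schedule.

    Durations that are not multiples of 30 s are rounded down with a warning;
    an empty schedule raises.
    """
    if not config.stage_schedule:
        raise ValueError("stage schedule is empty")
    stages: List[str] = []
    for stage, dur in config.stage_schedule:
        n_ep = int(dur // 30)
        if dur % 30:
            warnings.warn(f"schedule entry ({stage}, {dur}s) rounded down to {n_ep} epochs")
        stages.extend([stage] * n_ep)
    if not stages:
        raise ValueError("schedule contains no whole 30-s epoch")
    return Hypnogram(stages=stages)


def gen_modulator(
    duration_s: float,
    band: Tuple[float, float] = (0.001, 0.003),
    seed: int = 0,
) -> RawSignal:
    """Zero-mean, unit-variance band-limited Gaussian process at 1 Hz.

    Constructed by hard band-limiting white Gaussian noise in the frequency
    domain, then standardising; fully deterministic under ``seed``.
    """
    if duration_s < 300:
        raise ValueError("modulator needs at least 300 s")
    n = int(duration_s)
    rng = np.random.default_rng([int(seed), 10])
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    return RawSignal(x, rate=1.0, label="modulator", units="au")


def _envelope(base: np.ndarray, c: np.ndarray, gain: float, g: np.ndarray) -> np.ndarray:
    return base * (1.0 + gain * c * g)


def _per_second_arrays(
    config: SimConfig, hyp: Hypnogram, mod: RawSignal
) -> Tuple[List[str], np.ndarray, np.ndarray]:
    sec_stage = _stage_per_second(hyp, config.duration_s)
    c = np.array([config.coupling_per_stage[s] for s in sec_stage])
    g = _coupling_modulation(mod.samples[: len(sec_stage)])
    return sec_stage, c, g


def gen_eeg(config: SimConfig, hyp: Hypnogram, mod: RawSignal) -> RawSignal:
    """Stage-structured EEG: four band-limited noises with modulated envelopes.

    Each band is unit-RMS Gaussian noise band-passed to its range, scaled by
    a per-second envelope ``base_amp(stage) * (1 + c * gain_eeg * g(mod))``
    (linearly interpolated to the sampling grid), plus broadband sensor
    noise.  Delta base amplitude is largest in deep sleep, beta in wake.
    """
    from .eeg import EEG_BANDS

    rng = _rng(config, 20)
    fs = config.eeg_rate
    n = int(config.duration_s * fs)
    sec_stage, c, g = _per_second_arrays(config, hyp, mod)
    t_sec = np.arange(len(sec_stage), dtype=float)
    t = np.arange(n) / fs
    out = np.zeros(n)
    gain = config.system_gain["eeg"]
    for band, (lo, hi) in EEG_BANDS.items():
        noise = rng.standard_normal(n)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        carrier = sps.sosfilt(sos, noise)
        carrier /= max(carrier.std(), 1e-12)
        base = np.array([config.eeg_band_amplitudes[s][band] for s in sec_stage])
        env = _envelope(base, c, gain, g)
        out += carrier * np.interp(t, t_sec, env)
    out += config.eeg_noise_uv * rng.standard_normal(n)
    return RawSignal(out, rate=fs, label="O2-M1", units="uV")


def _gaussian_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def gen_ecg(config: SimConfig, hyp: Hypnogram, mod: RawSignal) -> Tuple[RawSignal, np.ndarray]:
    """Schematic ECG with LF/HF-modulated RR intervals; returns true R times.

    RR recursion: ``r_k = mean_rr * (1 + a_LF*(1 + c*gain*g(mod))*sin(2 pi
    f_LF t_k) + a_HF*sin(2 pi f_HF t_k) + eps_k)``.  The waveform is a train
    of Gaussian R complexes with P/T-like bumps plus white noise at
    ``ecg_snr_db``.  Only R-peak timing is physiological; the morphology is a
    template.  An RR excursion at or below 0.2 s raises.
    """
    rng = _rng(config, 30)
    fs = config.ecg_rate
    sec_stage, c_sec, g_sec = _per_second_arrays(config, hyp, mod)
    t_sec = np.arange(len(sec_stage), dtype=float)
    gain = config.system_gain["ecg"]
    lf_amp_t = config.a_lf * (1.0 + gain * c_sec * g_sec)
    # HF is anti-modulated (sympathovagal balance): a high modulator raises LF
    # and depresses HF, steepening the relative-power response
    hf_amp_t = config.a_hf * (1.0 - 0.7 * gain * c_sec * g_sec)

    times = [0.5]
    while times[-1] < config.duration_s - 1.5:
        tk = times[-1]
        a_lf = np.interp(tk, t_sec, lf_amp_t)
        a_hf = np.interp(tk, t_sec, hf_amp_t)
        r = config.mean_rr_s * (
            1.0
            + a_lf * np.sin(2 * np.pi * config.lf_hz * tk)
            + a_hf * np.sin(2 * np.pi * config.hf_hz * tk)
            + (config.rr_noise * rng.standard_normal() if config.rr_noise > 0 else 0.0)
        )
        if r <= 0.2:
            raise ValueError("RR excursion <= 0.2 s; reduce modulation amplitudes")
        times.append(tk + r)
    peaks = np.array(times)
    n = int(config.duration_s * fs)
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    w = int(0.12 * fs)
    for i, tk in enumerate(peaks):
        k = int(round(tk * fs))
        a, b = max(0, k - 3 * w), min(n, k + 3 * w)
        seg = t[a:b]
        ecg[a:b] += _gaussian_bump(seg, tk, 0.012)
        rr_prev = peaks[i] - peaks[i - 1] if i > 0 else config.mean_rr_s
        rr_next = peaks[i + 1] - peaks[i] if i + 1 < peaks.size else config.mean_rr_s
        ecg[a:b] += 0.12 * _gaussian_bump(seg, tk - 0.22 * rr_prev, 0.025)
        ecg[a:b] += 0.28 * _gaussian_bump(seg, tk + 0.30 * rr_next, 0.05)
    p_sig = float(np.mean(ecg**2))
    sigma = np.sqrt(p_sig / (10 ** (config.ecg_snr_db / 10.0)))
    ecg += sigma * rng.standard_normal(n)
    return RawSignal(ecg, rate=fs, label="ECG", units="mV"), peaks


def gen_bs(
    config: SimConfig, hyp: Hypnogram, mod: RawSignal
) -> Tuple[DualChannelAudio, np.ndarray]:
    """Dual-channel bowel sounds: Poisson tone bursts + correlated leakage.

    Burst rate follows ``stage_rate * (1 + c*gain*g(mod))``; each burst is a
    50-200 ms Hann-windowed cluster of tones whose centre frequency is drawn
    log-normally around 320 Hz and shifted multiplicatively by the modulator
    (high modulator -> higher-frequency bursts).  This spectral shift is what
    carries the coupling into the *relative* band powers, which are invariant
    to a pure rate change.  The noise channel is independent colored noise; a
    fixed 16-tap room response leaks it into the BS channel.
    """
    rng = _rng(config, 40)
    fs = config.bs_rate
    n = int(config.duration_s * fs)
    sec_stage, c_sec, g_sec = _per_second_arrays(config, hyp, mod)

    # ambient noise channel and its leakage into the BS channel
    ns = sps.sosfilt(
        sps.butter(2, [30.0, 2000.0], btype="bandpass", fs=fs, output="sos"),
        rng.standard_normal(n),
    ).astype(np.float64)
    ns *= config.ns_rms / max(ns.std(), 1e-12)
    h = rng.normal(0.0, 1.0, 16) * np.exp(-np.arange(16) / 4.0)
    h /= max(np.abs(h).sum(), 1e-12)
    bs = config.bs_leak * sps.lfilter(h, [1.0], ns)

    rate_t = np.array([config.bs_burst_rate_hz[s] for s in sec_stage])
    lam = np.clip(rate_t * (1.0 + config.system_gain["bs"] * c_sec * g_sec), 0.0, None)
    burst_times: List[float] = []
    for sec in range(len(sec_stage)):
        for _ in range(rng.poisson(lam[sec])):
            t0 = sec + rng.random()
            dur = rng.uniform(0.05, 0.2)
            if (t0 + dur) * fs >= n:
                continue
            shift = 1.1 * config.coupling_per_stage[sec_stage[sec]] * g_sec[sec]
            fc = float(np.clip(np.exp(np.log(320.0) + 0.20 * rng.standard_normal() + shift),
                               120.0, 950.0))
            m = int(dur * fs)
            tt = np.arange(m) / fs
            tone = np.zeros(m)
            for frac in (1.0, rng.uniform(1.05, 1.25)):
                tone += np.sin(2 * np.pi * fc * frac * tt + rng.uniform(0, 2 * np.pi))
            amp = 0.22 * np.exp(0.4 * rng.standard_normal())
            k = int(t0 * fs)
            bs[k : k + m] += amp * np.hanning(m) * tone
            burst_times.append(t0)
    bs += config.bs_noise_rms * rng.standard_normal(n)
    audio = DualChannelAudio(
        bs=RawSignal(bs, rate=fs, label="BS", units="au"),
        ns=RawSignal(ns, rate=fs, label="NS", units="au"),
    )
    return audio, np.array(sorted(burst_times))


def gen_activity(config: SimConfig, hyp: Hypnogram) -> Tuple[ActivitySeries, List[Tuple[float, float]]]:
    """Movement-intensity trace: near-zero baseline with episodic excursions.

    Movement episodes occur at a per-stage Poisson rate (highest awake), last
    3-10 s and exceed the 0.2 exclusion threshold by construction; episode
    intervals are returned as ground truth.
    """
    rng = _rng(config, 50)
    sec_stage = _stage_per_second(hyp, config.duration_s)
    n = len(sec_stage)
    values = np.abs(rng.normal(0.0, 0.02, n))
    intervals: List[Tuple[float, float]] = []
    for sec in range(n):
        rate = config.movement_rate_per_hour[sec_stage[sec]] / 3600.0
        if rng.random() < rate:
            dur = int(rng.uniform(3, 10))
            end = min(n, sec + dur)
            values[sec:end] += rng.uniform(0.4, 1.0)
            intervals.append((float(sec), float(end)))
    return ActivitySeries(values=values, rate=1.0), intervals


def gen_night(config: SimConfig) -> SyntheticNight:
    """Generate every channel of one night from a single config/seed."""
    hyp = gen_hypnogram(config)
    mod = gen_modulator(config.duration_s, config.modulator_band, config.seed)
    eeg = gen_eeg(config, hyp, mod)
    ecg, peaks = gen_ecg(config, hyp, mod)
    audio, bursts = gen_bs(config, hyp, mod)
    activity, moves = gen_activity(config, hyp)
    truth = GroundTruth(
        r_peak_times_s=peaks,
        bs_burst_times_s=bursts,
        modulator=mod,
        movement_intervals=moves,
        coupling_per_stage=dict(config.coupling_per_stage),
    )
    return SyntheticNight(
        config=config,
        hypnogram=hyp,
        eeg=eeg,
        ecg=ecg,
        audio=audio,
        activity=activity,
        truth=truth,
    )
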