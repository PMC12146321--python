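"""ECG R-peak detection and heart-rate-variability spectral power series.

Chain: band-pass ECG 0.5-40 Hz -> Haar stationary-wavelet R-peak detection
with an adaptive threshold -> RR-interval series -> 21-point/z>4 outlier
repair -> cubic-spline resampling to a uniform 8 Hz grid -> db12 wavelet
detrending -> sliding-window Burg autoregressive PSD -> relative power in
VLF (0.0033-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz), plus the
LF/HF ratio, at one sample per second.

The Burg window is 300 s, so each HRV power sample summarises autonomic
state over +/-150 s around its (window-centre) timestamp; the downstream
coupling analysis inherits that smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg as _burg

from .eeg import butterworth_bandpass
from .signal_io import BandPowerSeries, RawSignal

__all__ = [
    "HRV_BANDS",
    "RRISeries",
    "ResampledRRI",
    "detect_r_peaks",
    "correct_rri",
    "resample_rri",
    "detrend_rri",
    "burg_hrv_power",
    "hrv_band_power",
]

HRV_BANDS: Dict[str, Tuple[float, float]] = {
    "VLF": (0.0033, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.40),
}


@dataclass
class RRISeries:
    """R-peak times and the derived RR-interval (tachogram) series."""

    peak_times_s: np.ndarray
    quality_flags: np.ndarray = field(default=None)  # per-interval: kept/replaced
    _intervals: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.size >= 2 and not np.all(np.diff(self.peak_times_s) > 0):
            raise ValueError("peak times must be strictly increasing")
        if self._intervals is None:
            self._intervals = np.diff(self.peak_times_s)
        if self.quality_flags is None:
            self.quality_flags = np.array(["kept"] * self._intervals.size)
        if self.quality_flags.size != self._intervals.size:
            raise ValueError("quality_flags must match intervals")

    @property
    def intervals_s(self) -> np.ndarray:
        return self._intervals

    @property
    def interval_end_times_s(self) -> np.ndarray:
        return self.peak_times_s[1:]


@dataclass
class ResampledRRI:
    """RR series interpolated onto a uniform grid (default 8 Hz)."""

    values: np.ndarray
    rate: float
    start_s: float
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("resampled RRI must be finite")

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.values.size) / self.rate


def _haar_detection_function(x: np.ndarray, rate: float) -> np.ndarray:
    """Squared Haar stationary-wavelet details at the QRS scales (~5-25 Hz).

    Levels are chosen so their pass-bands (fs/2^(j+1) .. fs/2^j) cover the
    QRS energy; at 500 Hz that is levels 4 and 5 (15.6-31.2 and 7.8-15.6 Hz).
    Long signals are processed in chunks with overlap to bound memory.
    """
    lev_hi = max(1, int(np.round(np.log2(rate / 31.25))) + 1)  # ~ level 4 at 500 Hz
    levels = [lev_hi, lev_hi + 1]
    maxlev = max(levels)
    chunk = 1 << 20
    pad = 1 << (maxlev + 2)
    n = x.size
    det = np.empty(n)
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        a0 = max(0, c0 - pad)
        a1 = min(n, c1 + pad)
        seg = x[a0:a1]
        m = 1 << maxlev
        npad = (-seg.size) % m
        if npad:
            seg = np.concatenate([seg, seg[-1] * np.ones(npad)])
        coeffs = pywt.swt(seg, "haar", level=maxlev, trim_approx=True, norm=True)
        # coeffs = [cA_max, cD_max, ..., cD_1]
        d = np.zeros(seg.size)
        for lev in levels:
            d += coeffs[maxlev - lev + 1] ** 2
        det[c0:c1] = d[c0 - a0 : c0 - a0 + (c1 - c0)]
    return det


def detect_r_peaks(
    ecg: RawSignal,
    kappa: float = 0.3,
    refractory_s: float = 0.25,
    search_s: float = 0.05,
    prefilter: Tuple[float, float] = (0.5, 40.0),
) -> np.ndarray:
    """R-peak times (seconds) via Haar wavelet transform + adaptive threshold.

    The squared Haar detail coefficients form a detection function; the
    threshold is ``kappa`` times the 98th percentile of the detection function
    over a trailing 10-s window, floor-clamped at 0.1 times the global 98th
    percentile.  Candidate maxima are separated by a refractory period and
    refined to the maximum filtered-ECG sample within +/-``search_s``.

    A flat signal returns an empty array; rate below 250 Hz raises.
    """
    if ecg.rate < 250:
        raise ValueError("ECG rate must be >= 250 Hz for QRS detection")
    if ecg.duration_s < 10:
        raise ValueError("need at least 10 s of ECG")
    if np.ptp(ecg.samples) == 0:
        return np.array([])
    filt = butterworth_bandpass(ecg, *prefilter)
    det = _haar_detection_function(filt.samples, ecg.rate)
    # blockwise trailing 98th percentile (10-s blocks)
    blk = int(10 * ecg.rate)
    nblk = int(np.ceil(det.size / blk))
    bp = np.array([np.percentile(det[i * blk : (i + 1) * blk], 98) for i in range(nblk)])
    trailing = np.concatenate(([bp[0]], bp[:-1]))  # block i thresholded by block i-1
    level = np.maximum(np.repeat(trailing, blk)[: det.size], 0.1 * np.percentile(det, 98))
    thresh = kappa * level
    peaks, _ = sps.find_peaks(det, height=thresh, distance=int(refractory_s * ecg.rate))
    if peaks.size == 0:
        return np.array([])
    # refine to the maximum-amplitude sample of the filtered ECG
    w = int(round(search_s * ecg.rate))
    refined = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        a, b = max(0, p - w), min(filt.samples.size, p + w + 1)
        refined[i] = a + int(np.argmax(filt.samples[a:b]))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [int(refined[0])]
    min_gap = int(refractory_s * ecg.rate)
    for p in refined[1:]:
        if p - keep[-1] >= min_gap:
            keep.append(int(p))
        elif filt.samples[p] > filt.samples[keep[-1]]:
            keep[-1] = int(p)
    return ecg.start_offset + np.asarray(keep, dtype=float) / ecg.rate


def correct_rri(rri: RRISeries, window_points: int = 21, z_threshold: float = 4.0) -> RRISeries:
    """Replace local z-score outliers in the tachogram by the local mean.

    For each interval the mean and SD over a centred ``window_points`` window
    (shrunk symmetrically at the edges) are computed; intervals with
    ``|x - mu| / sigma > z_threshold`` are replaced by ``mu`` and flagged
    ``"replaced"``.  Windows with zero SD keep their intervals unchanged.
    """
    x = rri.intervals_s
    if x.size < 3:
        raise ValueError("need at least 3 intervals")
    half = window_points // 2
    out = x.copy()
    flags = np.array(["kept"] * x.size, dtype=object)
    for i in range(x.size):
        h = min(half, i, x.size - 1 - i)
        w = x[i - h : i + h + 1]
        mu = w.mean()
        sd = w.std(ddof=0)
        if sd > 0 and abs(x[i] - mu) / sd > z_threshold:
            out[i] = mu
            flags[i] = "replaced"
    return RRISeries(
        peak_times_s=rri.peak_times_s,
        quality_flags=np.asarray(flags),
        _intervals=out,
    )


def resample_rri(rri: RRISeries, rate: float = 8.0) -> ResampledRRI:
    """Cubic-spline interpolation of RR vs interval end-time onto ``rate`` Hz."""
    if rri.peak_times_s.size < 2:
        raise ValueError("need at least 2 peaks")
    t = rri.interval_end_times_s
    v = rri.intervals_s
    # anchor the uniform grid on a whole second so window-centre timestamps
    # downstream land on the common 1-s grid of the other power series
    start = float(np.ceil(t[0]))
    grid = start + np.arange(int(np.floor((t[-1] - start) * rate)) + 1) / rate
    if grid.size < 2:
        raise ValueError("RR support too short to resample")
    if t.size < 4:  # cubic spline needs 4 knots; fall back to linear
        return ResampledRRI(np.interp(grid, t, v), rate, start)
    cs = CubicSpline(t, v)
    return ResampledRRI(cs(grid), rate, start)


def detrend_rri(res: ResampledRRI, wavelet: str = "db12", cutoff_hz: float = 0.0033,
                level: Optional[int] = 10) -> ResampledRRI:
    """Subtract the slow wavelet-approximation trend from the resampled RRI.

    A multilevel ``wavelet`` decomposition is taken to ``level`` (default 10;
    at 8 Hz the approximation then covers < ~0.004 Hz, i.e. essentially below
    the VLF band).  Reconstructing the approximation alone gives the trend,
    which is subtracted.  Series too short for the requested depth use the
    maximal usable depth; a series shorter than one filter length raises.
    """
    x = res.values
    wav = pywt.Wavelet(wavelet)
    maxlev = pywt.dwt_max_level(x.size, wav.dec_len)
    if maxlev < 1:
        raise ValueError("series too short for wavelet detrending")
    if level is None:
        level = int(np.ceil(np.log2(res.rate / cutoff_hz)) - 1)
    use = min(level, maxlev)
    coeffs = pywt.wavedec(x, wav, level=use)
    trend_coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    trend = pywt.waverec(trend_coeffs, wav)[: x.size]
    return ResampledRRI(x - trend, res.rate, res.start_s, detrended=True)


def _ar_band_powers(x: np.ndarray, rate: float, order: int, edges: np.ndarray) -> np.ndarray:
    """Integrated Burg-AR PSD between consecutive ``edges`` (Hz)."""
    rho, sigma2 = _burg(x - x.mean(), order=order)
    nfft = 512
    a = np.zeros(nfft * 2)
    a[0] = 1.0
    a[1 : order + 1] = -rho
    h = np.fft.rfft(a)[: nfft + 1]
    f = np.arange(nfft + 1) * (rate / 2.0) / nfft
    psd = sigma2 / (rate * np.abs(h) ** 2)
    cum = np.concatenate(([0.0], np.cumsum((psd[1:] + psd[:-1]) / 2.0 * np.diff(f))))
    return np.diff(np.interp(edges, f, cum))


def burg_hrv_power(
    res: ResampledRRI,
    window_s: float = 300.0,
    step_s: float = 1.0,
    order: int = 16,
) -> List[BandPowerSeries]:
    """Sliding-window Burg AR relative powers: HRV-VLF/LF/HF and HRV-LFHF.

    Per window, the AR(``order``) PSD is integrated over each band and
    normalised by the total 0.0033-0.40 Hz power; the LF/HF ratio is flagged
    missing (NaN) wherever the HF integral is zero.  Output is one sample per
    ``step_s`` at window-centre timestamps.
    """
    n = res.values.size
    win = int(round(window_s * res.rate))
    step = int(round(step_s * res.rate))
    if n < win:
        raise ValueError("series shorter than the Burg window")
    edges = np.array([HRV_BANDS["VLF"][0], HRV_BANDS["VLF"][1], HRV_BANDS["LF"][1], HRV_BANDS["HF"][1]])
    n_out = (n - win) // step + 1
    powers = np.empty((n_out, 3))
    for i in range(n_out):
        seg = res.values[i * step : i * step + win]
        powers[i] = _ar_band_powers(seg, res.rate, order, edges)
    tot = powers.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(tot[:, None] > 0, powers / tot[:, None], np.nan)
        lfhf = np.where(powers[:, 2] > 0, powers[:, 1] / powers[:, 2], np.nan)
    time_s = res.start_s + np.arange(n_out) * step / res.rate + window_s / 2.0
    out = []
    for j, name in enumerate(["VLF", "LF", "HF"]):
        lo, hi = HRV_BANDS[name]
        out.append(BandPowerSeries("HRV", name, lo, hi, rel[:, j], time_s))
    out.append(BandPowerSeries("HRV", "LFHF", 0.04, 0.40, lfhf, time_s))
    return out


def hrv_band_power(
    ecg: RawSignal,
    window_s: float = 300.0,
    step_s: float = 1.0,
    order: int = 16,
) -> Tuple[List[BandPowerSeries], RRISeries]:
    """Full ECG chain: detect -> repair -> resample (8 Hz) -> detrend -> Burg."""
    peaks = detect_r_peaks(ecg)
    if peaks.size < 22:
        raise ValueError("too few beats detected for HRV analysis")
    rri = correct_rri(RRISeries(peak_times_s=peaks))
    res = detrend_rri(resample_rri(rri))
    return burg_hrv_power(res, window_s=window_s, step_s=step_s, order=order), rri
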