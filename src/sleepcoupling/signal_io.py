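"""Signal data model and file I/O for the coupling pipeline.

Raw polysomnography channels (EEG, ECG) travel in EDF; dual-channel
bowel-sound audio in 16-bit PCM WAV at 8 kHz; hypnogram, activity, band-power
and coupling tables in CSV.  All time axes are seconds from recording start
(lights-off); sample indexing is 0-based and windows are half-open
``[t, t + dt)``.

Hypnograms are stored with AASM labels ``{W, N1, N2, N3, R}`` and grouped at
load time into the four analysis stages: Awake, LS (N1+N2), DS (N3), REM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "RawSignal",
    "Hypnogram",
    "ActivitySeries",
    "DualChannelAudio",
    "BandPowerSeries",
    "read_edf",
    "write_edf",
    "read_wav_dual",
    "write_wav_dual",
    "read_hypnogram",
    "write_hypnogram",
    "read_activity",
    "write_activity",
    "read_power_series",
    "write_power_series",
    "read_coupling_records",
    "write_coupling_records",
    "AASM_STAGES",
    "GROUPED_STAGES",
    "group_stage",
]

AASM_STAGES = ("W", "N1", "N2", "N3", "R")
GROUPED_STAGES = ("Awake", "LS", "DS", "REM")

_GROUP_MAP = {"W": "Awake", "N1": "LS", "N2": "LS", "N3": "DS", "R": "REM"}


def group_stage(label: str) -> str:
    """AASM label -> grouped analysis stage (Awake / LS / DS / REM)."""
    try:
        return _GROUP_MAP[label]
    except KeyError:
        raise ValueError(f"unknown AASM stage label {label!r}") from None


@dataclass
class RawSignal:
    """Uniformly sampled 1-D physiological signal.

    Attributes
    ----------
    samples : ndarray
        Signal values; must be finite.
    rate : float
        Sampling rate in Hz (> 0).
    label : str
        Channel name (e.g. ``"O2-M1"``).
    units : str
        Physical units (``"uV"`` for EEG, ``"mV"`` for ECG, ``"au"`` for audio).
    start_offset : float
        Seconds from recording start to the first sample.
    """

    samples: np.ndarray
    rate: float
    label: str = ""
    units: str = ""
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.samples.size) / self.rate


@dataclass
class Hypnogram:
    """30-s epoch sleep-stage labels (AASM) with a grouped view."""

    stages: List[str]
    epoch_seconds: int = 30

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in AASM_STAGES]
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(set(bad))}")

    @property
    def grouped(self) -> List[str]:
        return [_GROUP_MAP[s] for s in self.stages]

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_seconds

    def grouped_stage_at(self, t_s: float) -> Optional[str]:
        """Grouped stage covering time ``t_s``; None outside the record."""
        i = int(t_s // self.epoch_seconds)
        if t_s < 0 or i >= len(self.stages):
            return None
        return _GROUP_MAP[self.stages[i]]

    def stage_runs(self) -> List[Tuple[str, float, float]]:
        """Maximal runs of a single grouped stage as (stage, start_s, end_s)."""
        runs: List[Tuple[str, float, float]] = []
        g = self.grouped
        start = 0
        for i in range(1, len(g) + 1):
            if i == len(g) or g[i] != g[start]:
                runs.append((g[start], start * self.epoch_seconds, i * self.epoch_seconds))
                start = i
        return runs


@dataclass
class ActivitySeries:
    """Non-negative body-movement intensity trace (accelerometry-derived)."""

    values: np.ndarray
    rate: float
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.values.size) / self.rate


@dataclass
class DualChannelAudio:
    """Bowel-sound recorder output: abdomen-facing (bs) + ambient noise (ns)."""

    bs: RawSignal
    ns: RawSignal

    def __post_init__(self) -> None:
        if self.bs.rate != self.ns.rate:
            raise ValueError("bs and ns must share a sampling rate")
        if self.bs.samples.size != self.ns.samples.size:
            raise ValueError("bs and ns must have equal length")


@dataclass
class BandPowerSeries:
    """1-sample-per-second band-power trace for one (family, band).

    ``family`` is one of EEG / HRV / BS; EEG powers are absolute (uV^2), HRV
    and BS powers are relative fractions (LF/HF ratio excepted).  Timestamps
    are window centres, strictly increasing at 1-s steps; missing windows are
    NaN.
    """

    family: str
    band: str
    f_lo: float
    f_hi: float
    values: np.ndarray
    time_s: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values.shape != self.time_s.shape:
            raise ValueError("values and time_s must have equal length")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < -1e-12):
            raise ValueError("band power must be non-negative")

    @property
    def name(self) -> str:
        return f"{self.family}-{self.band}"


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_edf(path, signals: Sequence[RawSignal], record_s: float = 1.0) -> None:
    """Write signals to a plain EDF file (16-bit, one data-record block layout).

    Signals may have different rates but must share an integer number of
    samples per ``record_s``-second record; short tails are zero-padded to a
    whole record.  Physical min/max are taken from the data so the 16-bit
    quantisation step is ``(max - min) / 65535`` per channel.
    """
    path = Path(path)
    nsamp = []
    for s in signals:
        sp = s.rate * record_s
        if abs(sp - round(sp)) > 1e-9:
            raise ValueError(f"rate {s.rate} not commensurate with record_s={record_s}")
        nsamp.append(int(round(sp)))
    n_records = int(np.ceil(max(s.samples.size / s.rate for s in signals) / record_s))
    nchan = len(signals)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (nchan + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{record_s:g}", 8),
            pad(str(nchan), 4),
        ]
    )
    phys_lo, phys_hi, scaled = [], [], []
    for s in signals:
        lo = float(np.min(s.samples))
        hi = float(np.max(s.samples))
        if hi <= lo:
            hi = lo + 1.0
        phys_lo.append(lo)
        phys_hi.append(hi)
        gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (hi - lo)
        dig = np.round((s.samples - lo) * gain + _EDF_DIG_MIN).astype("<i2")
        scaled.append(dig)
    fields: List[bytes] = []
    for get, width in [
        (lambda i: signals[i].label or f"ch{i}", 16),
        (lambda i: "", 80),
        (lambda i: signals[i].units, 8),
        (lambda i: f"{phys_lo[i]:.8g}"[:8], 8),
        (lambda i: f"{phys_hi[i]:.8g}"[:8], 8),
        (lambda i: str(_EDF_DIG_MIN), 8),
        (lambda i: str(_EDF_DIG_MAX), 8),
        (lambda i: "", 80),
        (lambda i: str(nsamp[i]), 8),
        (lambda i: "", 32),
    ]:
        fields.extend(pad(str(get(i)), width) for i in range(nchan))
    with open(path, "wb") as fh:
        fh.write(header + b"".join(fields))
        for r in range(n_records):
            for i, dig in enumerate(scaled):
                chunk = dig[r * nsamp[i] : (r + 1) * nsamp[i]]
                if chunk.size < nsamp[i]:
                    fillv = np.round(
                        (0.0 - phys_lo[i])
                        * (_EDF_DIG_MAX - _EDF_DIG_MIN)
                        / (phys_hi[i] - phys_lo[i])
                        + _EDF_DIG_MIN
                    ).astype("<i2")
                    chunk = np.concatenate(
                        [chunk, np.full(nsamp[i] - chunk.size, fillv, dtype="<i2")]
                    )
                fh.write(chunk.tobytes())


def read_edf(path, channel_labels: Optional[Sequence[str]] = None) -> Dict[str, RawSignal]:
    """Read EDF channels via MNE; returns ``{label: RawSignal}``.

    Values are returned in the channel's native physical units as stored in
    the EDF header (MNE's volt conversion is undone for uV/mV channels).
    Requesting a channel absent from the file raises ``KeyError``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # unreadable header
        raise ValueError(f"not a readable EDF file: {path}") from exc
    available = list(raw.ch_names)
    wanted = list(channel_labels) if channel_labels is not None else available
    missing = [c for c in wanted if c not in available]
    if missing:
        raise KeyError(f"channel(s) {missing} not in {available}")
    # native units from the EDF physical-dimension field
    units = _edf_units(path, available)
    out: Dict[str, RawSignal] = {}
    for ch in wanted:
        idx = available.index(ch)
        data = raw.get_data(picks=[ch])[0]
        unit = units.get(ch, "")
        scale = {"uV": 1e6, "mV": 1e3, "V": 1.0}.get(unit)
        if scale is not None and raw.info["chs"][idx]["unit"] != 0:
            data = data * scale if unit != "V" else data
        out[ch] = RawSignal(
            samples=np.asarray(data, dtype=float),
            rate=float(raw.info["sfreq"]),
            label=ch,
            units=unit,
        )
    return out


def _edf_units(path: Path, labels: Sequence[str]) -> Dict[str, str]:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        nchan = int(hdr[252:256].decode().strip())
        fh.read(16 * nchan + 80 * nchan)  # labels + transducer
        dims = [fh.read(8).decode("ascii", "replace").strip() for _ in range(nchan)]
    file_labels = _edf_labels(path, nchan)
    return {lab: dim for lab, dim in zip(file_labels, dims) if lab in labels}


def _edf_labels(path: Path, nchan: int) -> List[str]:
    with open(path, "rb") as fh:
        fh.read(256)
        return [fh.read(16).decode("ascii", "replace").strip() for _ in range(nchan)]


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------


def write_wav_dual(path, audio: DualChannelAudio) -> None:
    """Write the two channels as a 16-bit PCM stereo WAV (bs first, ns second).

    Samples are expected in [-1, 1]; they are clipped then scaled to int16.
    """
    data = np.stack([audio.bs.samples, audio.ns.samples], axis=1)
    data = np.clip(data, -1.0, 1.0)
    wavfile.write(Path(path), int(audio.bs.rate), np.round(data * 32767.0).astype(np.int16))


def read_wav_dual(path) -> DualChannelAudio:
    """Read a 2-channel PCM WAV: channel 0 -> bs, channel 1 -> ns.

    Raises ``ValueError`` for mono (or >2-channel) files.
    """
    rate, data = wavfile.read(Path(path))
    if data.ndim != 2 or data.shape[1] != 2:
        nch = 1 if data.ndim == 1 else data.shape[1]
        raise ValueError(f"expected a 2-channel WAV, got {nch} channel(s)")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483647.0
    else:
        data = data.astype(np.float64)
    bs = RawSignal(data[:, 0], rate=float(rate), label="BS", units="au")
    ns = RawSignal(data[:, 1], rate=float(rate), label="NS", units="au")
    return DualChannelAudio(bs=bs, ns=ns)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def write_hypnogram(path, hyp: Hypnogram) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp.stages)), "stage": hyp.stages}
    ).to_csv(Path(path), index=False)


def read_hypnogram(path) -> Hypnogram:
    """Read an ``epoch_index,stage`` CSV of AASM labels.

    An unknown label raises ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(Path(path))
    if "stage" not in df.columns:
        raise ValueError("hypnogram CSV needs a 'stage' column")
    if "epoch_index" in df.columns:
        df = df.sort_values("epoch_index")
    stages = [str(s).strip() for s in df["stage"]]
    for row, s in enumerate(stages):
        if s not in AASM_STAGES:
            raise ValueError(f"unknown stage label {s!r} at row {row}")
    return Hypnogram(stages=stages)


def write_activity(path, act: ActivitySeries) -> None:
    pd.DataFrame({"time_s": act.times(), "value": act.values}).to_csv(
        Path(path), index=False
    )


def read_activity(path) -> ActivitySeries:
    """Read a ``time_s,value`` CSV; rate inferred from the time grid."""
    df = pd.read_csv(Path(path))
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        rate = 1.0
    else:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("activity time grid must be uniform")
        rate = 1.0 / dt[0]
    return ActivitySeries(values=v, rate=rate, start_offset=float(t[0]) if t.size else 0.0)


def write_power_series(path, series: Iterable[BandPowerSeries]) -> None:
    """Write band-power series as long CSV ``time_s,family,band,power``."""
    frames = [
        pd.DataFrame(
            {"time_s": s.time_s, "family": s.family, "band": s.band, "power": s.values}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False, float_format="%.12g")


def read_power_series(path) -> List[BandPowerSeries]:
    df = pd.read_csv(Path(path))
    out = []
    for (family, band), g in df.groupby(["family", "band"], sort=False):
        g = g.sort_values("time_s")
        out.append(
            BandPowerSeries(
                family=str(family),
                band=str(band),
                f_lo=float("nan"),
                f_hi=float("nan"),
                values=g["power"].to_numpy(dtype=float),
                time_s=g["time_s"].to_numpy(dtype=float),
            )
        )
    return out


def write_coupling_records(path, records: pd.DataFrame) -> None:
    """Write coupling records (`pair,band_x,band_y,stage,window_start_s,mic`)."""
    cols = ["pair", "band_x", "band_y", "stage", "window_start_s", "mic"]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    records[cols].to_csv(Path(path), index=False, float_format="%.12g")


def read_coupling_records(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
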