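"""Night-level coupling analysis: windows, exclusions and MIC matrices.

The night is cut into non-overlapping, stage-homogeneous 5-min windows
(anchored at each maximal run of a grouped sleep stage; sub-300-s remainders
are dropped).  Windows touching a 30-s epoch that contains body movement
(activity above threshold 0.2) are excluded, as are windows with under 80 %
of their 300 one-per-second sample pairs available.  For every surviving
window the maximal information coefficient is computed for each band pair of

* BHC (brain-heart): 4 EEG x 4 HRV bands,
* BGC (brain-gut):   4 EEG x 5 BS bands,
* HGC (heart-gut):   4 HRV x 5 BS bands,

i.e. 56 coupling records per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mic import MICParams, compute_mic
from .signal_io import ActivitySeries, BandPowerSeries, Hypnogram

__all__ = [
    "AnalysisWindow",
    "PAIR_FAMILIES",
    "segment_stage_windows",
    "exclude_movement",
    "align_series",
    "compute_coupling",
]

log = logging.getLogger(__name__)

WINDOW_S = 300.0
MIN_PAIRS = 240  # 80 % coverage of a 5-min window

PAIR_FAMILIES: Dict[str, Tuple[str, str]] = {
    "BHC": ("EEG", "HRV"),
    "BGC": ("EEG", "BS"),
    "HGC": ("HRV", "BS"),
}


@dataclass
class AnalysisWindow:
    """One stage-homogeneous 5-min analysis window."""

    start_s: float
    end_s: float
    stage: str
    excluded: bool = False
    reason: Optional[str] = None  # movement / boundary / missing-data

    def __post_init__(self) -> None:
        if abs((self.end_s - self.start_s) - WINDOW_S) > 1e-9:
            raise ValueError("analysis windows are 300 s long")

    def exclude(self, reason: str) -> None:
        if not self.excluded:
            self.excluded = True
            self.reason = reason


def segment_stage_windows(hyp: Hypnogram, total_duration_s: Optional[float] = None) -> List[AnalysisWindow]:
    """Tile every maximal grouped-stage run with non-overlapping 300-s windows.

    Remainders shorter than 300 s are dropped (logged as boundary loss).
    """
    total = hyp.duration_s if total_duration_s is None else min(hyp.duration_s, total_duration_s)
    windows: List[AnalysisWindow] = []
    dropped = 0
    for stage, start, end in hyp.stage_runs():
        end = min(end, total)
        t = start
        while t + WINDOW_S <= end + 1e-9:
            windows.append(AnalysisWindow(start_s=t, end_s=t + WINDOW_S, stage=stage))
            t += WINDOW_S
        if end - t > 1e-9:
            dropped += 1
    if dropped:
        log.info("dropped %d sub-300-s stage-run remainders (boundary rule)", dropped)
    return windows


def exclude_movement(
    windows: Sequence[AnalysisWindow],
    activity: ActivitySeries,
    threshold: float = 0.2,
    epoch_s: float = 30.0,
) -> List[AnalysisWindow]:
    """Flag windows overlapping any movement-contaminated 30-s epoch.

    An epoch is contaminated when any activity sample within it exceeds
    ``threshold``; a window with no activity coverage at all is excluded as
    missing data.  Returns the same window objects, flagged in place.
    """
    t = activity.times()
    contaminated = set()
    above = activity.values > threshold
    for ti in t[above]:
        contaminated.add(int(ti // epoch_s))
    for w in windows:
        cov = (t >= w.start_s) & (t < w.end_s)
        if not np.any(cov):
            w.exclude("missing-data")
            continue
        e0 = int(w.start_s // epoch_s)
        e1 = int(np.ceil(w.end_s / epoch_s))
        if any(e in contaminated for e in range(e0, e1)):
            w.exclude("movement")
    return list(windows)


def align_series(
    a: BandPowerSeries, b: BandPowerSeries, window: AnalysisWindow
) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    """Pair two 1-Hz series by timestamp inside the window; None if sparse.

    Samples whose (window-centre) timestamps fall in ``[start_s, end_s)`` are
    matched exactly by timestamp; pairs with a missing (NaN) value on either
    side are dropped.  Fewer than 240 valid pairs (the 80 % coverage rule)
    yields None, and the caller excludes the window as missing data.
    Unsorted timestamps raise.
    """
    for s in (a, b):
        if s.time_s.size > 1 and not np.all(np.diff(s.time_s) > 0):
            raise ValueError("series timestamps must be strictly increasing")
    ta, tb = a.time_s, b.time_s
    sel_a = (ta >= window.start_s) & (ta < window.end_s)
    sel_b = (tb >= window.start_s) & (tb < window.end_s)
    common, ia, ib = np.intersect1d(ta[sel_a], tb[sel_b], return_indices=True)
    if common.size == 0:
        return None
    va = a.values[sel_a][ia]
    vb = b.values[sel_b][ib]
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < MIN_PAIRS:
        return None
    return va[ok], vb[ok]


def compute_coupling(
    eeg_series: Sequence[BandPowerSeries],
    hrv_series: Sequence[BandPowerSeries],
    bs_series: Sequence[BandPowerSeries],
    windows: Sequence[AnalysisWindow],
    params: Optional[MICParams] = None,
) -> pd.DataFrame:
    """One MIC per (pair, band_x, band_y, window): the full coupling table.

    Every non-excluded window contributes exactly 16 + 20 + 20 = 56 records;
    a window whose pairs cannot be aligned is excluded as missing data.
    Missing band series raise a configuration error naming the family.
    """
    params = params or MICParams()
    families = {"EEG": list(eeg_series), "HRV": list(hrv_series), "BS": list(bs_series)}
    for fam, expected in (("EEG", 4), ("HRV", 4), ("BS", 5)):
        if len(families[fam]) != expected:
            raise ValueError(
                f"{fam} family needs {expected} band series, got {len(families[fam])}"
            )
    rows = []
    included = 0
    for w in windows:
        if w.excluded:
            continue
        window_rows = []
        usable = True
        for pair, (fx, fy) in PAIR_FAMILIES.items():
            for sx in families[fx]:
                for sy in families[fy]:
                    aligned = align_series(sx, sy, w)
                    if aligned is None:
                        usable = False
                        break
                    x, y = aligned
                    res = compute_mic(x, y, params)
                    window_rows.append(
                        {
                            "pair": pair,
                            "band_x": sx.name,
                            "band_y": sy.name,
                            "stage": w.stage,
                            "window_start_s": w.start_s,
                            "mic": res.mic,
                        }
                    )
                if not usable:
                    break
            if not usable:
                break
        if not usable:
            w.exclude("missing-data")
            continue
        included += 1
        rows.extend(window_rows)
    if included == 0:
        log.warning("no analysis window survived exclusion; empty coupling table")
    return pd.DataFrame(
        rows, columns=["pair", "band_x", "band_y", "stage", "window_start_s", "mic"]
    )
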