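"""Model-style front end: fit a whole night, get a results object back.

``SleepCouplingModel`` bundles the five inputs of one night (EEG, ECG,
dual-channel bowel-sound audio, hypnogram, activity trace); ``fit()`` runs
the full extraction and coupling chain and returns a
``SleepCouplingResults`` carrying the per-window MIC records, the stage
comparisons and diagnostic bookkeeping, in the spirit of a statsmodels
``Model.fit() -> Results`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bowel, eeg as eeg_mod, hrv as hrv_mod, pipeline, stats as stats_mod
from .mic import MICParams
from .signal_io import (
    ActivitySeries,
    BandPowerSeries,
    DualChannelAudio,
    Hypnogram,
    RawSignal,
)

__all__ = ["SleepCouplingModel", "SleepCouplingResults"]


class SleepCouplingModel:
    """Brain-heart-gut coupling analysis of one polysomnography night.

    Parameters
    ----------
    eeg, ecg : RawSignal
        Occipital EEG (uV) and ECG at >= 250 Hz.
    audio : DualChannelAudio
        8 kHz bowel-sound + ambient-noise channels.
    hypnogram : Hypnogram
        30-s AASM staging covering the recording.
    activity : ActivitySeries
        Movement-intensity trace used for segment exclusion.
    """

    def __init__(
        self,
        eeg: RawSignal,
        ecg: RawSignal,
        audio: DualChannelAudio,
        hypnogram: Hypnogram,
        activity: ActivitySeries,
    ) -> None:
        self.eeg = eeg
        self.ecg = ecg
        self.audio = audio
        self.hypnogram = hypnogram
        self.activity = activity

    @classmethod
    def from_night(cls, night) -> "SleepCouplingModel":
        """Build from a :class:`~sleepcoupling.synthetic.SyntheticNight`."""
        return cls(night.eeg, night.ecg, night.audio, night.hypnogram, night.activity)

    @classmethod
    def from_files(
        cls,
        edf_path,
        wav_path,
        hypnogram_path,
        activity_path,
        eeg_channel: str = "O2-M1",
        ecg_channel: str = "ECG",
    ) -> "SleepCouplingModel":
        """Build from on-disk EDF / WAV / CSV inputs."""
        from . import signal_io as io

        channels = io.read_edf(edf_path, [eeg_channel, ecg_channel])
        return cls(
            eeg=channels[eeg_channel],
            ecg=channels[ecg_channel],
            audio=io.read_wav_dual(wav_path),
            hypnogram=io.read_hypnogram(hypnogram_path),
            activity=io.read_activity(activity_path),
        )

    def extract_band_power(self) -> Dict[str, List[BandPowerSeries]]:
        """Run the three per-system extraction chains (EEG / HRV / BS)."""
        eeg_series = eeg_mod.eeg_band_power(self.eeg)
        hrv_series, rri = hrv_mod.hrv_band_power(self.ecg)
        bs_series = bowel.bs_chain(self.audio)
        self._rri = rri
        return {"EEG": eeg_series, "HRV": hrv_series, "BS": bs_series}

    def fit(
        self,
        mic_params: Optional[MICParams] = None,
        movement_threshold: float = 0.2,
    ) -> "SleepCouplingResults":
        """Extract band powers, build windows, compute the coupling table."""
        series = self.extract_band_power()
        duration = min(self.hypnogram.duration_s, self.eeg.duration_s)
        windows = pipeline.segment_stage_windows(self.hypnogram, duration)
        pipeline.exclude_movement(windows, self.activity, threshold=movement_threshold)
        records = pipeline.compute_coupling(
            series["EEG"], series["HRV"], series["BS"], windows, mic_params
        )
        return SleepCouplingResults(
            model=self, records=records, windows=windows, band_power=series
        )


@dataclass
class SleepCouplingResults:
    """Fitted coupling table with stage-wise summaries and diagnostics."""

    model: SleepCouplingModel
    records: pd.DataFrame
    windows: List[pipeline.AnalysisWindow]
    band_power: Dict[str, List[BandPowerSeries]]

    @property
    def n_windows_included(self) -> int:
        return sum(1 for w in self.windows if not w.excluded)

    @property
    def exclusion_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for w in self.windows:
            if w.excluded:
                out[w.reason] = out.get(w.reason, 0) + 1
        return out

    def summary(self) -> pd.DataFrame:
        """Per-cell stage comparison table (median/IQR, KW, Dunn-Bonferroni)."""
        return stats_mod.summarize(self.records)

    def contrast_hgc_bgc(self) -> pd.DataFrame:
        """Per-stage heart-gut vs brain-gut pooled contrast."""
        return stats_mod.contrast_hgc_bgc(self.records)

    def stage_medians(self) -> pd.DataFrame:
        """Median MIC per (pair, stage): the headline coupling profile."""
        return (
            self.records.groupby(["pair", "stage"], sort=False)["mic"]
            .median()
            .unstack("stage")
        )

    def plot_stage_profile(self, ax=None):
        """Heat map of median MIC per system pair and sleep stage."""
        import matplotlib.pyplot as plt

        tab = self.stage_medians()
        cols = [s for s in stats_mod.STAGE_ORDER if s in tab.columns]
        tab = tab[cols]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        im = ax.imshow(tab.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(tab.columns)), tab.columns)
        ax.set_yticks(range(len(tab.index)), tab.index)
        for i in range(tab.shape[0]):
            for j in range(tab.shape[1]):
                ax.text(j, i, f"{tab.iloc[i, j]:.2f}", ha="center", va="center",
                        color="w", fontsize=8)
        ax.figure.colorbar(im, ax=ax, label="median MIC")
        ax.set_title("Coupling by sleep stage")
        return ax
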