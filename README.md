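# sleepcoupling

Sleep-stage-stratified **brain-heart-gut coupling** from continuous
physiological signals. The package turns one night of polysomnography —
occipital EEG, ECG and dual-channel bowel-sound audio, with a 30-s
hypnogram and a body-movement trace — into band-power time series per organ
system and quantifies their pairwise dependence with the **maximal
information coefficient (MIC)** inside stage-homogeneous 5-min windows,
then compares coupling across Awake, light sleep (LS), deep sleep (DS) and
REM with non-parametric statistics. It is aimed at network-physiology and
sleep researchers who want a tested, reproducible reference pipeline for
multi-system coupling, including a synthetic polysomnography generator with
*known* injected coupling for validation.

## The statistic at the core

For two equal-length series X, Y the maximal information coefficient is

```
MIC(X, Y) = max_{n_x * n_y <= B(n, alpha)}  max_G I_G(X, Y) / log2 min(n_x, n_y)
```

the largest grid mutual information over axis-aligned `n_x x n_y` grids,
normalised to [0, 1], with the grid size bounded by `B(n, alpha) = n^alpha`
(alpha = 0.6). The search equipartitions one axis, optimises the other by
exact dynamic programming over rank-midpoint cuts, terminates cut insertion
with a chi-square independence test (p < 0.01) on each new boundary, and
revisits the equipartitioned boundaries with a backward
removal-or-reposition pass — a BackMIC-style estimator. A brute-force
enumeration oracle for small inputs pins its correctness down to 1e-12.

Three coupling families are scored per 5-min window: **BHC** (4 EEG bands x
4 HRV bands), **BGC** (4 EEG x 5 bowel-sound bands) and **HGC** (4 HRV x 5
BS bands) — 56 MIC values per window. EEG power is absolute (delta, theta,
alpha, beta; 4-s Welch windows at 1-s steps); HRV power is relative (VLF,
LF, HF + LF/HF from a 300-s sliding Burg AR spectrum of the cleaned,
8-Hz-resampled, db12-detrended RR series); bowel-sound power is relative in
five bands (VLF–HF, 0.5–1,000 Hz) after 100–1,000 Hz band-passing, NLMS
ambient-noise cancellation against the reference microphone, and
sym6/Birge-Massart wavelet denoising.

## Worked example

```python
from sleepcoupling.synthetic import SimConfig, gen_night
from sleepcoupling.model import SleepCouplingModel

# one 90-min synthetic night; coupling per stage is known by construction:
# c(Awake)=0.9, c(LS)=0.6, c(DS)=0.3, c(REM)=0.7, heart/gut injected
# stronger than brain
night = gen_night(SimConfig(duration_s=5400, seed=11))
res = SleepCouplingModel.from_night(night).fit()

print(res.n_windows_included, res.exclusion_counts)
print(res.stage_medians().round(3))
print(res.contrast_hgc_bgc()[["stage", "median_hgc", "median_bgc", "p_adj", "sig"]])
```

which prints (seed 11):

```
13 {'missing-data': 2, 'movement': 3}
stage     LS     DS    REM  Awake
pair
BHC    0.290  0.142  0.316  0.392
BGC    0.139  0.092  0.151  0.135
HGC    0.313  0.200  0.242  0.302
   stage  median_hgc  median_bgc     p_adj  sig
0  Awake       0.302       0.135  1.02e-04  ***
1     LS       0.313       0.139  4.89e-16  ***
2     DS       0.200       0.092  6.60e-18  ***
3    REM       0.242       0.151  5.58e-10  ***
```

Thirteen 5-min windows survive exclusion (three contained body movement,
two lacked HRV coverage). The median-MIC table recovers the injected
ordering — every system pair couples most weakly in deep sleep and rebounds
after it — and heart-gut coupling exceeds brain-gut coupling in every stage
at Bonferroni-adjusted p < 0.05, exactly the asymmetry the generator
injects. `res.summary()` gives the full per-band-pair table (median/IQR per
stage, Kruskal-Wallis H and p, Dunn-Bonferroni pairwise p with ns/*/**/***
glyphs), and `res.plot_stage_profile()` draws the median-MIC heat map.

The same pipeline runs from files (EDF + WAV + CSVs) via
`SleepCouplingModel.from_files(...)` or the CLI:

```bash
sleepcoupling simulate night/ --seed 11 --duration-s 5400
sleepcoupling preprocess-eeg night/psg.edf eeg.csv
sleepcoupling preprocess-ecg night/psg.edf hrv.csv
sleepcoupling preprocess-bs  night/bowel.wav bs.csv
sleepcoupling couple eeg.csv hrv.csv bs.csv night/hypnogram.csv night/activity.csv records.csv
sleepcoupling stats records.csv summary.csv --contrast-csv contrast.csv
```

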