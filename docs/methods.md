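# Methods

This package quantifies brain-heart-gut coupling across sleep stages from
three continuous overnight signals — occipital EEG, ECG, and abdominal
bowel-sound audio — using the maximal information coefficient (MIC) between
band-power time series, stratified by 30-s sleep staging grouped into Awake,
light sleep (LS = N1+N2), deep sleep (DS = N3) and REM. This note records the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Signal chains

**EEG.** The O2-M1 channel (500 Hz, uV) is band-passed 0.5-40 Hz with a
fourth-order Butterworth filter applied forward-backward (zero phase: the
coupling analysis is alignment-sensitive, so band-power timestamps must not
be skewed by group delay). A 4-s Welch window sliding in 1-s steps yields
absolute power (uV^2) in delta 0.5-4, theta 4-8, alpha 8-13 and beta
13-30 Hz, one sample per second at window-centre timestamps. Welch internals
per window: 2-s Hamming sub-segments, 50 % overlap, next-power-of-two FFT —
0.5 Hz resolution is ample for bands at least 3.5 Hz wide. Band edges are
half-open `[f_lo, f_hi)`, so 4 Hz belongs to theta. A "4-s window, 1-s
overlap" could also be read as a 3-s step; the 1-s step is the reading
consistent with a 1-Hz-resolution output series and is the default, with the
step exposed as a parameter.

**ECG → HRV.** After the same 0.5-40 Hz band-pass, R peaks are detected from
the squared Haar stationary-wavelet detail coefficients at the two scales
whose pass-bands cover roughly 8-31 Hz at 500 Hz sampling (the QRS energy
range). The adaptive threshold is 0.3 x the 98th percentile of the detection
function over a trailing 10-s window, floor-clamped at 0.1 x the global 98th
percentile; candidate maxima respect a 250-ms refractory period and are
refined to the maximum filtered-ECG sample within +/-50 ms. The RR series is
repaired with a centred 21-point window: an interval more than 4 local SDs
from the local mean is replaced by that mean (zero-SD windows keep their
values). Repaired intervals are cubic-spline interpolated against interval
end-times onto a uniform 8 Hz grid anchored on a whole second (so HRV
timestamps land on the common 1-s grid downstream), then detrended by
subtracting the level-10 db12 wavelet approximation (at 8 Hz the
approximation band is below ~0.004 Hz, i.e. essentially below VLF; level 11
would be needed to fall strictly below 0.0033 Hz, but the difference only
moves a sliver of VLF into the removed trend). A wavelet transform is not
defined on the irregular tachogram, so detrending follows resampling; the
reverse order can be forced via the module functions. Per 300-s window
sliding in 1-s steps, a Burg autoregressive spectrum (order 16 — a common
HRV choice resolving VLF/LF/HF at 8 Hz; configurable) is integrated over VLF
0.0033-0.04, LF 0.04-0.15 and HF 0.15-0.40 Hz and normalised by the
0.0033-0.40 Hz total; LF/HF is reported as a ratio and flagged missing where
the HF integral vanishes. Each HRV sample therefore summarises autonomic
state over +/-150 s around its timestamp — an asymmetry with the 4-s EEG/BS
windows that is inherent to the design and documented rather than "fixed".

**Bowel sounds.** The 8 kHz BS channel is band-passed 100-1,000 Hz
(order 4, zero phase); the NLMS adaptive filter (64 taps, step 0.001,
energy-normalised update with a regulariser of 1e-8 x the reference power
scale) subtracts the component correlated with the ambient-noise reference
channel; a 6-level sym6 decomposition is soft-thresholded with Birge-Massart
level-dependent thresholds and reconstructed. The Birge-Massart rule keeps
`n_j = M / (J + 2 - j)^alpha` coefficients at level j (j = J coarsest),
alpha = 3, with the retained-coefficient budget M set to a quarter of the
signal length; thresholds are capped at the universal level sigma *
sqrt(2 ln n) with sigma estimated from the finest-level detail MAD, so a
noiseless signal passes through essentially unchanged. Relative power is
then computed per 4-s window (1-s steps) in VLF 0.5-200, LF 200-300, MF1
300-400, MF2 400-500 and HF 500-1,000 Hz, normalised by the 0.5-1,000 Hz
total. The VLF band is integrated exactly as printed although its lower
edge lies below the 100 Hz high-pass corner; the 0.5-100 Hz portion carries
only filter leakage.

## The maximal information coefficient

For series x, y of length n, MIC is the maximum over axis-aligned grids
with `n_x * n_y <= B(n, alpha) = n^alpha` (alpha = 0.6, so B ~ 30 at the
pipeline's n = 300) of the grid mutual information normalised by
`log2 min(n_x, n_y)`. Cut candidates are midpoints between consecutive
order statistics — the estimator is exactly invariant under strictly
increasing transforms, and ties (which share a rank) cannot be separated.

The search: one axis is rank-equipartitioned into m bins; the other axis is
optimised by an exact dynamic program over cut candidates for every bin
count k; both orientations are run, so the result is symmetric. Cut
acceptance is chi-square-terminated: for growing k, every boundary of the
optimal k-partition must pass a Pearson independence test on the 2 x m
sub-table formed by splitting at that boundary (df = m - 1, columns with
expected count < 1 merged for the test only) at p < 0.01; the first k that
fails stops the growth on that axis. The equipartitioned axis is then
revisited backwards: each boundary may be removed or moved to another
candidate between its flanking boundaries when the normalised score does not
decrease (a moved boundary must itself pass the chi-square test); bins are
never added. With a single interior boundary (m = 2) this backward search
degenerates to a full scan over candidate positions, which makes the search
*exact* for every grid shape whose smaller side is 2 — and hence exactly
equal to the brute-force oracle for bounds B <= 6, the basis of the
oracle-equivalence test.

Cost controls, all deterministic: for n > 128 the free-axis candidate set is
subsampled evenly to max(24, 3k) positions and the m = 2 scan to 24
positions (below that threshold the candidate set is complete and the
per-shape search exact); backward pruning is applied for m <= 6 — finer
equipartitions keep their rank-balanced boundaries, since their larger
normaliser makes them rarely decisive and pruning there costs far more than
it recovers. Degenerate inputs (a constant series) define MIC = 0 with a
flag. The exhaustive oracle (guarded to n <= 40, B <= 9) enumerates every
grid on the same candidate set and is used only in tests.

Observed behaviour at the pipeline's window size (n = 300): independent
uniform pairs average MIC ~ 0.05-0.10; autocorrelated but independent
band-power-like series sit near 0.1-0.2 (serial correlation inflates any
plug-in dependence measure — stage comparisons are unaffected because every
stage inherits the same inflation); noiseless functional relations score
>= 0.99.

## Windowing, exclusion and statistics

Maximal runs of a grouped stage are tiled with non-overlapping 300-s windows
from the run start; remainders under 300 s are dropped. A window is excluded
if any 30-s epoch it touches contains an activity sample above 0.2 (the
movement rule), or if fewer than 240 of its 300 per-second sample pairs
align across the two series being coupled (an 80 % coverage rule covering
the HRV series' late start and missing values). Each surviving window
contributes 56 records: 16 BHC (EEG x HRV), 20 BGC (EEG x BS), 20 HGC
(HRV x BS).

Stage comparisons are non-parametric throughout: Lilliefors-corrected
Kolmogorov-Smirnov normality screening (the uncorrected K-S is a flag away),
median (IQR) summaries, the tie-corrected Kruskal-Wallis omnibus across the
four stages, and Dunn's pairwise z-tests on pooled ranks with Bonferroni
adjustment over the six stage pairs (the post-hoc SPSS runs under "all
pairwise comparisons"; plain pairwise rank tests are available behind a
flag). The heart-gut vs brain-gut contrast pools all HGC and all BGC values
within each stage and applies a two-sided Mann-Whitney test, Bonferroni
x4. Records are pooled over windows (and, in tests, nights) with no
subject-level random effect — a deliberate simplification matching the
epoch-pooling analysis design, and a known limitation.

## The synthetic night

Real overnight recordings are not distributed with the package, so
validation runs on a generator whose coupling is known by construction. One
shared slow Gaussian modulator u(t) (band-limited 0.001-0.003 Hz, unit
variance, 1 Hz) drives all three systems through a clipped linear map
g(u) = clip(0.6 u, -0.95, 0.95) and a per-stage coupling coefficient c:
default c(Awake) = 0.9, c(LS) = 0.6, c(DS) = 0.3, c(REM) = 0.7 — wake
strongest, deep sleep weakest, REM rebounding. Per-system gains scale the
injection; the default brain gain of 0.35 (heart and gut at 1.0) injects
heart-gut coupling stronger than brain-gut coupling.

* **EEG**: four band-limited Gaussian noises with per-second envelopes
  `base_amp(stage) * (1 + 0.35 c g(u))` plus broadband sensor noise; delta
  base amplitude is largest in DS (40 uV) and beta largest in wake.
* **ECG**: an RR recursion `r_k = 0.9 s * (1 + a_LF(t) sin(2 pi 0.1 t_k) +
  a_HF(t) sin(2 pi 0.25 t_k) + eps_k)` with `a_LF = 0.07 (1 + c g(u))` and
  HF *anti*-modulated, `a_HF = 0.035 (1 - 0.7 c g(u))` — a schematic
  sympathovagal balance that steepens the relative-power response. The
  waveform is a Gaussian R-complex template with P/T-like bumps plus white
  noise at a configurable SNR; only R timing is physiological.
* **Bowel sounds**: Poisson bursts (50-200 ms Hann-windowed tone clusters)
  at stage-dependent rates (0.2-0.3 per second) modulated by `(1 + c g(u))`,
  with centre frequencies drawn log-normally around 320 Hz and shifted
  multiplicatively by `exp(1.1 c g(u))`. The spectral shift matters: the BS
  pipeline outputs *relative* band powers, and a pure rate change scales all
  bands together and cancels in the ratio — the modulator must move spectral
  content, not just event counts, to be recoverable. A fixed 16-tap room
  response leaks the independent colored noise of the reference channel into
  the BS channel; sensor noise is added on top.
* **Activity**: near-zero baseline with Poisson movement episodes (3-10 s,
  amplitude 0.4-1.0, rates highest awake) returned as ground-truth
  intervals.

The modulator band deserves its own paragraph. The HRV chain averages any
modulation over its 300-s Burg window, i.e. multiplies the modulation
spectrum by sinc(300 f): a band at 0.01-0.05 Hz (several cycles per 5-min
window) is annihilated outright, and a band inside the first side-lobe
(~0.0033-0.0067 Hz) comes through sign-inverted in some windows and upright
in others, decorrelating the HRV series from the other two systems
window-by-window. Placing the band at 0.001-0.003 Hz — entirely below the
first sinc zero at 1/300 Hz — passes 10-80 % of the modulation with a
consistent sign, at the price of only ~0.3-0.9 modulator cycles per 5-min
window. MIC handles the resulting within-window co-trends well (monotone
dependence is its easiest case). Generator constants (gains, rates, noise
levels, the spectral-shift depth) were calibrated once against the
generator's own published behaviours — e.g. extracted delta power must
correlate > 0.6 with the modulator at c = 1 — and then frozen.

What passing these tests shows: the full pipeline, run end-to-end on
signals it has never seen, recovers a known stage-dependent coupling
ordering, the injected HGC > BGC asymmetry, and a ~5 % false-positive rate
when no coupling exists. What it does not show: anything about real EEG
microstructure (no spindles or K-complexes), real bowel-sound acoustics
beyond band occupancy and burst statistics, real ECG morphology, or
between-subject variability — the generator pools one "subject" per night
and the statistics pool epochs exactly as the analysis design does.

## Problem sizes and determinism

Synthetic nights in the test suite are 90 min (three coupled seeds + two
null seeds); the acceptance script uses two coupled 2-h nights and one null
night. These sizes give roughly 4-6 analysis windows per stage per night
(about 26-28 windows per night, 56 MIC values each) and keep a full run in
the minutes range; the hourly stage template allocates 15 min each to
Awake/LS/DS/REM in runs that are multiples of 300 s, so windows tile stage
runs without boundary loss. All generators are deterministic functions of a
single seed; the MIC estimator contains no randomness at all. R-peak
detection fidelity is checked on one hour of ECG at 10 dB SNR (sensitivity
and precision >= 0.99 at +/-20 ms); detection is amplitude-scale-invariant
by construction.

## Known limitations

* The backward-search variant here is conservative (never adds bins,
  score-non-decreasing moves only) and is not claimed to replicate any
  particular published implementation's cut-by-cut behaviour; the
  exhaustive-enumeration oracle pins down its correctness where both run.
* The chi-square termination tests a cut *selected by maximising MI*, so
  its nominal level is optimistic; it is a stopping heuristic, not an
  inference procedure.
* Band-power series are serially correlated (overlapping windows), which
  inflates absolute MIC levels; all conclusions are comparative across
  stages or system pairs, never about absolute coupling strength.
* The EDF writer is minimal (16-bit, single-block layout, no annotations);
  reading goes through MNE and accepts any EDF it can parse.
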