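# Methods

`neosleep` implements a multimodal sleep-state classification pipeline for
preterm infants monitored in the NICU, together with a synthetic-recording
simulator that stands in for clinical data (which are not publicly
available for privacy reasons). This note records the models, parameter
choices and numerical conventions, and what the synthetic experiments do and
do not demonstrate.

## The classification problem

Preterm-infant behaviour is scored per 30-s epoch into active sleep (AS,
REM-like), quiet sleep (QS, non-REM-like) and a merged caretaking + wake
class (CTW). The pipeline extracts 91 features per epoch from four sources —
ECG-derived heartbeats (34), respiratory effort (41), the
cardiorespiratory-interaction series (8) and video-based actigraphy (8) —
and classifies epochs with an extremely-randomized-trees (ET) ensemble under
leave-one-subject-out (LOSO) cross-validation, balancing each training fold
with SMOTE. Tasks: the 3-class problem and the pairwise problems AS vs QS,
QS vs CTW, AS vs CTW and Sleep (AS+QS) vs CTW; feature sets: Motion,
ECG-Resp-CRI, and all families combined.

## Synthetic recordings

The simulator reproduces the statistical structure the analysis assumes, not
waveform-level physiology.

**Hypnogram.** A semi-Markov chain over {AS, QS, CTW}: bout lengths are
geometric in epochs (means AS 20, QS 10, CTW 5), and the stationary state
mix targets AS 72 %, QS 12 %, CTW 16 % — the skewed distribution typical of
NICU recordings. Entry weights are first corrected (fixed-point on the
embedded chain's stationary distribution) for the no-self-transition bias,
then tilted at each bout boundary by `exp(25 x (target - realized fraction))`.
This self-correction leaves bout-length statistics untouched but pins the
realized mix: an i.i.d. bout-type draw would still wander by ±7 % after 1000
epochs, which would make short-cohort experiments needlessly seed-sensitive.

**Heartbeats.** Inter-beat (RR) intervals are Gaussian per state, truncated
at half the state mean. Defaults are literature-typical for ~30-35 weeks
postmenstrual age, not values from any specific cohort: AS 375 ± 20 ms
(~160 bpm), QS 430 ± 8 ms (~140 bpm, steadier), CTW 365 ± 24 ms.
Decelerations arrive as a Poisson process (QS 1.0/min, AS 0.5/min,
CTW 0.2/min) and prolong a run of 3-6 intervals by 30 %. An optional
ECG-like trace places a Gaussian QRS template (8 ms SD) at each R time on
white noise (SD 0.05); with noise disabled the R-peak detector recovers
every beat to ±1 sample, which the tests use as a round-trip check.

**Respiration.** Concatenated breath templates: each breath is a rising
half-cosine (inhale, 40 % of the period) followed by a falling half-cosine
(exhale). Breath period and amplitude are drawn per breath with
state-dependent jitter and CV — QS regular and shallow (48/min, CV 6 %),
AS irregular and deep (60/min, CV 25 %, amplitude 1.4x QS), CTW most
irregular. This is a deterministic template model, sufficient to make
peak/trough, flow/volume and regularity features non-trivial; it contains no
apnea, sighs, or movement artefacts.

**Motion.** Movement bursts arrive as a per-epoch Poisson process
(CTW 12/min >> AS 2/min >> QS 0.3/min), each a half-sine pulse of 0.25-1.5 s
with exponentially distributed amplitude (CTW mean 3x sleep); the trace is
exactly zero between bursts. The parameter geometry deliberately mirrors the
physiological separability structure: cardiorespiratory parameters separate
AS from QS strongly but AS from CTW weakly, while motion separates CTW from
sleep strongly but AS from QS weakly — so the directional experiments below
test whether the pipeline recovers that structure, not whether it can
memorize it.

**Cohorts.** `simulate_cohort` adds per-subject multiplicative offsets
(CV 5 %) on mean RR, breathing rate and burst rate, shared across states, so
LOSO folds face genuine between-subject shift.

## Preprocessing

ECG and respiratory effort are Z-scored once per recording (never per
epoch); motion counts keep their native nonnegative scale. `Wake` and
`Caretaking` merge into `CTW`; `Unknown` epochs are excluded; trailing
partial windows are dropped. Epoch windows are half-open `[30i, 30(i+1))`
with 0-based indices, so no sample or R peak is assigned twice. R-peak
detection (used only when peak times are not supplied) is Pan-Tompkins
style: 5-40 Hz band-pass, squared derivative, 120-ms integration, adaptive
threshold, 200-ms refractory period.

## Features

The registry (`neosleep.features.registry`, exportable as CSV) fixes all 91
names, families and order. Points where the published feature inventory is
ambiguous, and how this package resolves them:

* **Cardiac (34).** HRV band edges are configurable with neonatal-convention
  defaults: VLF 0.01-0.04, LF 0.04-0.2, HF 0.2-1.0, plus extended sHF
  1.0-1.5 and uHF 1.5-2.0 Hz (neonatal heart rates reach 2.5-3 Hz). The RR
  tachogram is linearly resampled at 4 Hz, mean-detrended, Welch-estimated
  and band-integrated; intervals outside 200-750 ms are excluded from all
  HRV statistics. Decelerations are operationalized as runs of >= 2 beats at
  >= 1.1x a 15-beat running-median baseline (the source text names the
  features but defines no thresholds). SampEn uses m = 2, r = 0.2 SD;
  SampEn-AUC integrates over r/SD in {0.10 ... 0.30} and is missing whenever
  any grid point is undefined; QSE = SampEn + ln(2r). LZ complexity
  (median binarization, LZ76 exhaustive parsing, normalized by log2(n)/n) is
  computed on the NN series and on the ECG decimated to 125 Hz — at 500 Hz
  the binarized sequence mostly counts noise crossings and the parse cost
  grows quadratically for no information gain. The inventory is completed to
  34 with standard time-domain HRV statistics (mean/median/min/max/range/CV
  of NN, SDNN, RMSSD, SDSD, pNN10/20/50, HR mean/SD/min/max), each
  individually named.
* **Respiratory (41).** Band edges VLF 0.01-0.05, LF 0.05-0.15, HF
  0.15-0.5 Hz. Breath segmentation: prominence-filtered extrema (0.2 x epoch
  SD, minimum spacing 0.5 s) with alternation enforced by keeping the more
  extreme of same-type neighbours; a breath is trough -> peak -> next trough.
  "Volume" and "flow" are trapezoidal effort integrals and amplitude/duration
  ratios — chest impedance is uncalibrated, so they are unitless proxies.
  The enumerable inventory yields 39 features; the two remaining slots are
  the breath-wise variants of the inhale:exhale time- and flow-ratio
  features (the ratio-of-medians variants fill the primary slots).
* **CRI (8).** The CRI series samples the Z-scored effort signal at each
  R-peak time (linear interpolation). Natural visibility graphs use the
  *strict* criterion (collinear points block visibility) and the real,
  unevenly spaced R-peak times as the time axis (index mode is available);
  differencing whitens slow trends before the DVG. Features: VG degree
  mean/SD, DVG degree mean/SD, degree assortativity (plain VG), local
  clustering mean/SD, SampEn of the degree sequence in temporal order
  (defined as 0 for regular graphs). Epochs with < 4 beats yield missing
  values.
* **Motion (8).** Mean, SD, sum, EWMA-smoothed nonzero count
  (alpha = 0.3, state carried across consecutive epochs, first epoch = raw)
  and linear-interpolation percentiles P25/P50/P75/P95. When raw video is
  the input, per-frame motion is thresholded 16x16-block differencing (2 %
  of dynamic range) — a deliberately simple front end, since all epoch
  features consume only one scalar per frame.

Missing values (too few beats/breaths, undefined entropies) propagate as NaN
through extraction and are median-imputed per fold, with medians fitted on
the training partition only.

## Modeling and evaluation

ET uses scikit-learn's `ExtraTreesClassifier` with 100 trees, no depth
limit, Gini impurity, one seed per fold; importances are the impurity-based
(Gini) importances, collected per fold and ranked by mean. SMOTE raises
every class to the majority count: each synthetic row is
`x + u (x_nn - x)`, `u ~ U[0,1]`, with neighbours found among the k = 5
nearest same-class rows by Euclidean distance on standardized features
(k shrinks for tiny classes; singleton classes are duplicated with a
warning). Oversampling runs strictly inside each LOSO fold after the
subject split — the fold loop is the only caller, so no synthetic or
duplicated row can reach a test partition. Metrics: accuracy, Cohen's
kappa (`(p_o - p_e)/(1 - p_e)`, 0 by convention when `p_e = 1`), one-vs-rest
sensitivity/precision/specificity, and AUC via the tie-corrected
Mann-Whitney rank statistic, reported per fold (mean ± SD over subjects) and
pooled over epochs. A stacking/meta-classifier layer is deliberately not
implemented.

## Numerical choices

* Welch spectra are zero-padded (respiration nfft = 4096, tachogram 2048) so
  the narrow VLF bands contain integration bins; a 30-s window cannot truly
  resolve 0.01-0.05 Hz, so VLF power reflects leakage of the slowest
  resolvable content and is documented as such.
* SampEn follows Richman-Moorman (strict `< r`, self-matches excluded, both
  template counts over the first N-m templates); ApEn follows Pincus
  (`<= r`, self-matches included). Both match exhaustive brute-force
  implementations exactly on every tested input.
* LZ76 parses with `bytes.find` (C-speed scan); a constant series of length
  >= 2 is 2 phrases by definition (first symbol, then one reproducible
  remainder).
* Recording CSVs store floats with 17 significant digits and are read back
  with round-trip parsing, so write/read is bit-exact.

## Problem sizes

Cohort-level tests and the acceptance script use 8 subjects x 90 epochs
(45 min each) with 3 seed replicates — chosen so every state appears in
every subject and LOSO statistics stabilize, while a full run completes in
minutes on one CPU. `SimConfig` defaults to 589 epochs (~4.9 h), the typical
full recording length, for library use.

## What passing tests show — and what they do not

On synthetic cohorts the pipeline reproduces the qualitative pattern
expected from the physiology encoded in the generator: combined features
beat cardiorespiratory-only and motion-only for the 3-class task;
cardiorespiratory features win AS vs QS; motion features win AS vs CTW and
Sleep vs CTW; label shuffling drives mean LOSO kappa to ~0. Absolute kappas
on synthetic data are substantially higher than what is achievable on real
NICU recordings — the generator contains no electrode artefacts, signal
dropouts, annotation noise, apnea, or caregiver interference, and its
states are conditionally stationary within epochs. The synthetic results
therefore validate the pipeline's correctness and its ability to recover a
known separability structure, not clinical performance.

Other limitations: the video front end is block differencing, not a
recursive-search motion estimator; no artefact/quality indexing; no
calibrated tidal volume; HRV/respiratory band edges and entropy parameters
are convention-based defaults, all configurable.
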