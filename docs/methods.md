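# Methods

This note documents the analysis model, the choices that were genuinely
open, and what the synthetic cohort does and does not establish.

## Epochs, windowing and the common rate

Interictal epochs are nominally 300 s, ictal epochs 58 s spanning
[−30 s, +28 s) around electrical onset.  All recordings are brought to
256 Hz by polyphase antialiasing resampling at the exact rational ratio
(`scipy.signal.resample_poly`); this is the only signal conditioning —
no filtering, re-referencing or artefact removal is performed anywhere,
so class differences cannot be artefacts of a filter choice.

Features are computed in non-overlapping 2-s windows (512 samples).  A
58-s ictal epoch contains 29 raw windows: 15 before onset and 14 after.
To retain a symmetric 14 + 14, one pre-onset edge window must be
discarded; we drop the window most distant from onset, [−30, −28), to
preserve peri-onset information (`drop_edge="earliest"`; the alternative
of dropping [−2, 0) is selectable with `drop_edge="latest"`).  All
sample intervals are half-open and 0-based.

## Post-onset normalisation and series resampling

Seizure-related change is expressed relative to the pre-onset baseline
per (channel, feature):

    Post(w) ← (Post(w) − mean(Pre)) / (mean(Post) + mean(Pre))

Only the 14 normalised post-onset values enter the observation table.
The denominator can vanish for signed features (e.g. skewness); such
values are flagged missing (NaN) rather than imputed, and dropped when
models are fitted.  Normalisation is applied per ictal recording, not
pooled over a patient's seizures.

Interictal feature series (~150 values) are downsampled to 28 by
polyphase FIR resampling at the exact rational ratio (14/75 for 150)
with a Kaiser(β = 12) lowpass and line-extension padding; the high β
keeps passband ripple below 1e-7 so constant series pass through
unchanged.  A linear-interpolation fallback (`method="linear"`) exists
for cross-implementation checks.  The resulting observation counts per
contact — 28 × interictal recordings + 14 × ictal recordings — make the
two epoch types comparable.

## The 34-feature battery

Four families: 5 moments, 11 complexity, 12 frequency, 6 network
(registry is data-driven; the default has exactly 34 entries and can be
reduced or replaced).  Parameter choices that were open:

* **Moments** — variance uses the n−1 denominator; skewness/kurtosis are
  the standardized central moments (kurtosis non-excess, Gaussian → 3).
* **Entropies** — ApEn (Pincus: self-matches included) and SampEn
  (Richman–Moorman: excluded) use m = 2, r = 0.2·sd, Chebyshev distance,
  the standard conventions.  Permutation entropy: order 3, delay 1,
  normalised by log 6.  Lempel–Ziv: median binarisation, LZ76
  exhaustive-history count normalised by n/log2 n.
* **Fractal dimensions** — Higuchi with kmax = 8; Katz from amplitude
  path length and maximal excursion from the first sample (a monotone
  line gives exactly 1).  Hurst exponent from first-order DFA over box
  sizes 4–64.
* **Spectra** — Hann periodogram of the 512-sample window (0.5-Hz
  resolution); band powers are bin sums over half-open conventional
  clinical bands 1–4 / 4–8 / 8–13 / 13–30 / 30–60 / 60–120 Hz, bounded
  by the 128-Hz Nyquist.  Mean/median frequency and the 95% spectral
  edge are restricted to 1–120 Hz.  The energy ratio is
  (beta + low-γ + high-γ) / (delta + theta + alpha).  Spectral entropy
  is computed on the segment-averaged (Welch) spectrum of the window
  rather than the raw periodogram: the exponential bin distribution of a
  single periodogram biases normalised entropy down by
  (1 − γ)/ln n ≈ 0.08 even for white noise, whereas the 7-segment
  average keeps the flat-spectrum value near 1.
* **Network** — per window, mean absolute Pearson correlation with all
  other channels, and coherence node strength (mean magnitude-squared
  coherence, Welch estimate from 0.5-s Hann segments at 50% overlap,
  i.e. 7 segments per 2-s window) in delta/theta/alpha/beta/gamma
  (30–120 Hz).  Note the estimator's independence bias: E[msc] ≈ 1/7
  for unrelated channels; node strengths must be compared against that
  floor, not against zero.  Eight 0.5-s segments at exactly 50% overlap
  would need 576 samples and so cannot fit a 2-s window; 7 is the
  maximum.

Degenerate windows (zero variance) yield NaN for the features that are
undefined there; NaN is the package-wide missing flag.  Observation rows
missing >50% of features are dropped at table building, and remaining
incomplete rows are dropped per model fit (counts logged).

## Classification

The classification unit is the contact; its observation rows are the
retained windows.  The classifier is a bagged decision-tree ensemble
(50 trees, √34 ≈ 5 features per split, scikit-learn
`RandomForestClassifier`), scored by AUC on ensemble vote fractions.

**Balancing.**  EZ contacts are ~12.9% of contacts, so every
classification down-samples non-EZ *contacts* (not rows) to the EZ
contact count and the whole procedure is repeated (default 1000×,
reduced in desk runs) before averaging.

**Within-patient.**  Stratified 10-fold CV grouped by contact — all rows
of a contact share a fold, so no contact ever appears on both sides of a
split.  Two deliberate choices here:

* AUC is computed on the *pooled* out-of-fold votes rather than averaged
  over per-fold AUCs: with few contacts per class, grouped folds often
  contain a single class and per-fold AUC is undefined.
* The training contacts are re-balanced *within each fold*: holding out
  a contact leaves the remaining classes unequal, which systematically
  biases the ensemble against the held-out class and centres the chance
  null visibly below 0.5.  Restoring balance per fold removes that
  artefact; with it, the empirical null mean sits at 0.500 ± 0.02.

**Cross-time.**  Train on all interictal rows of balanced contacts, test
on all ictal rows (or the reverse).  When the two directions are
compared, per-contact row counts can be equalised between epoch types by
subsampling (`equalize=True`).

**Cross-patient.**  Leave-one-patient-out within an epoch type, with
contact-level balancing in the pooled training patients; optional
per-patient feature z-scoring (off by default).  A test patient with a
single class yields an undefined AUC and is logged, not imputed.

**Chance.**  Contact labels are permuted within patient (preserving each
patient's class balance) and the *full scheme* is re-run per shuffle
with a reduced number of balance repeats; defaults 1000 shuffles
(200 in desk runs).

**Contributions.**  For each feature, its column in the held-out rows is
permuted (default 20 draws) and the votes re-scored; the contribution is
max(0, AUC − AUC_permuted), averaged over repeats and draws, reported
raw and normalised to sum 1.  Permuting at the test side measures what
the fitted ensemble actually uses.  Redundant informative features split
their contribution — each copy's drop is smaller than a lone feature's.

**Seeds.**  One master seed; per-repeat/per-shuffle/per-patient
substreams are spawned deterministically (`numpy.random.SeedSequence`),
so every result is exactly reproducible.

## Bayes factors and correlations

BF10 for one-sample/paired and two-sample t statistics uses the JZS
prior (Cauchy on effect size, default scale √2/2, the common "medium"
default; configurable) via the one-dimensional integral over the
Zellner–Siow g representation, evaluated with adaptive quadrature after
mapping (0, ∞) → (0, 1); convergence is enforced at 1e-6 relative error
and validated in tests against a fine-grid trapezoid oracle and an
independent reference implementation.  Evidence bins: ≥10 / ≥3 / (1/3,
3) / ≤1/3 / ≤1/10, boundaries assigned to the stronger bin.  Pearson
correlations use the t-transform two-sided p-value.

## Synthetic cohort

The generator plants exactly the structure the analysis is designed to
detect, with per-patient channel counts drawn from N(106, 38²) clipped
at 16, EZ fraction 12.87%, native rates cycling through 256/512/1024 Hz
(exercising the resampling stage), 2 interictal epochs of 300 s and 1–5
ictal epochs of 58 s per patient:

* background: unit-SD Gaussian 1/f^α noise (α = 1) by spectral shaping,
  independent per channel plus a small common term (mix 0.05);
* EZ channels: amplitude ×`variance_gain` (default 2; a gain of g
  multiplies variance by g²), biphasic 70-ms spikes at Poisson times
  (default 0.5 Hz, 6 SD), and burst-modulated 30–90 Hz gamma of which a
  fraction `shared_gamma_mix` (default 0.5) comes from one common
  source — that shared source is what raises within-EZ coherence;
* ictal epochs: pre-onset is statistically identical to the interictal
  background; post-onset EZ channels show ~8 s of low-voltage fast
  activity (amplitude suppression plus 60–120 Hz noise) followed by a
  linearly growing rhythmic spike-wave component (default 3 Hz).
  Setting both ictal gains to zero makes post-onset indistinguishable
  from pre-onset, which the tests exploit as a null.

Default effect sizes are tuning choices (amplitude scalings of clinical
seizures are not standardised); they are exposed in `EffectSpec` and
chosen so that the planted classes are clearly separable at the default
gains and exactly exchangeable when all gains are zero.  Engel-style
outcome labels are cosmetic metadata.

What the generator does **not** emulate: biophysical neural-mass
dynamics, true spike/HFO morphology variability, non-stationary sleep
structure, artefacts, volume conduction or montage effects.  Passing
tests therefore establish that the pipeline's machinery is correct and
calibrated (labels recovered when planted, chance when absent), not that
any particular clinical AUC would be attained on real recordings.

## Small-sample behaviour of the permutation null

At realistic contact counts the shuffled-label null centres on 0.5
(106 contacts: 0.494 ± 0.005 over 200 shuffles).  At desk scale it does
not: with only k epileptogenic contacts per balanced sample, shuffled
labels are drawn without replacement, so conditioning on a held-out
contact's label makes its feature-space neighbours slightly more likely
to carry the *opposite* training label — a finite-population
anti-correlation that biases the null a few hundredths below 0.5
(measured: 0.474 at 30 contacts, 0.480 at 64, 0.494 at 106, with
planted effects; 0.486 at 30 contacts even with no effects).  Chance
calibration claims are therefore made, and tested, at the cohort's
default ~106-contact scale; desk-scale nulls are still useful as
scheme-matched reference bands but should not be read as exactly 0.5.

## Problem sizes in tests and the acceptance script

Most test fixtures use desk-scale cohorts — 16–24 channels, 60-s
interictal epochs, 1–2 seizures, reduced balance repeats/shuffles —
chosen as the smallest sizes at which the planted-effect properties are
stable; the chance-calibration check uses a 106-contact patient for the
reason above.  The acceptance script uses one 106-channel patient with
full-length 300-s interictal epochs, 200 label shuffles and 1 balance
repeat per shuffle.  The full-scale defaults (1000 repeats, 1000
shuffles) remain the package defaults and are reachable by config.

## Known limitations

* The exact identity of all 34 features in the source battery is not
  fixed by any single convention; the registry ships 19 canonically
  named features plus 15 standard members of the same four families, and
  is replaceable wholesale via `FeatureRegistry`.
* Band-power features are absolute (not relative) powers; correlation
  strength is mean *absolute* correlation.
* With very few contacts per class, contact-level AUC over balanced
  samples is coarse (few distinct values); row-level AUC is the primary
  statistic and both are reported.
* Bayes-factor ANOVA over clinical factors (outcome, region, pathology,
  modality) requires a real cohort and is out of scope.
* Reading clinical EDF/BrainVision exports directly is not implemented;
  cohorts are consumed in the documented directory layout
  (float32-binary or TSV signal containers with JSON sidecars,
  BIDS-iEEG-style `channels.tsv`/`events.tsv`).
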