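# Methods

This note records the model, the parameter choices, and the numerical and
design decisions behind `egmfrac`, at the level of detail a maintainer or
reviewer needs to audit or change them.

## Estimator

**Preprocessing.**  Each record is (1) divided by its whole-record RMS,
(2) low-pass filtered with a 3rd-order Butterworth at 300 Hz, (3) wavelet
denoised, (4) cut into consecutive non-overlapping 1-s epochs (trailing
remainder discarded).  The RMS step makes the whole chain invariant to
the absolute amplitude of the recording (verified to 1e-9 relative in the
tests); it is computed on the whole record, before epoching, because
normalization is a per-recording operation while the epoch is the unit of
analysis.  Filtering is zero-phase (forward–backward `sosfiltfilt`):
causal filtering would smear the sharp biphasic deflections whose
geometry the embedding is supposed to capture.  Note the
forward–backward pass squares the magnitude response, so the net gain at
the 300 Hz cutoff is 1/2 rather than 1/√2; the −3 dB point of the
single-pass design is exactly at the cutoff.  The denoiser is a `db4`
decomposition of depth 4 with soft thresholding of all detail levels at
the universal threshold σ√(2 ln N), σ estimated as MAD(finest
details)/0.6745 — a standard high-frequency denoiser; wavelet, depth and
rule are exposed in `PreprocConfig`.  A noise-free input (threshold 0) is
passed through unchanged.

**CGCD.**  Per epoch: rescale to unit peak-to-peak amplitude, delay-embed
with dimension `m` and lag `τ`, keep the **first** `Nref` delay vectors,
and evaluate the correlation integral at the two resolutions
`r_cg·e^{−δ}` and `r_cg·e^{+δ}`; the coarse-grained correlation dimension
is the symmetric finite difference of ln C against ln r between those two
points.  Conventions that needed fixing:

* `r_cg = 0.5 · SD(epoch) / ptp(epoch)`, and pair distances are computed
  on the unit-ptp rescaled epoch, so the resolution and the distances
  share one scale and the estimator is invariant to positive amplitude
  rescaling (an alternative — r_cg on the raw scale — would break that).
* The pair count uses a strict inequality (Θ(0) = 0).  Ties at exactly r
  are measure-zero for real signals; fixing the convention makes the
  estimator exactly reproducible and oracle-testable.
* δ = 0.1 in ln-r, i.e. the slope is a centered difference over a
  ±10% band around r_cg.  Symmetric log-space offsets make the estimator
  an unbiased-to-first-order local slope; δ is exposed in
  `EmbeddingConfig`.
* If C is zero at either evaluation point the epoch's CGCD is
  **undefined** (would be infinite); undefined epochs are excluded from
  the record median, and a record is unusable only when every epoch is
  undefined.  If C is equal at both points (a plateau), the slope is 0.
* Reference vectors are the first `Nref` in index order — deterministic
  and, on 1-s epochs, empirically indistinguishable from a seeded random
  draw (`mode='random'` is retained for that comparison).
* Pair distances use an exact O(Nref²) computation (334² ≈ 56k pairs per
  epoch); no spatial index is warranted at this size.

**Defaults** (all in `EmbeddingConfig`): `m = 4`, `τ = 8` samples at
1 kHz, `Nref = 334` (one third of a 1-s epoch), δ = 0.1.  These are the
operating point established for 1-s bipolar atrial EGM epochs: τ at the
first minimum of the mutual information of such recordings, Nref at the
smallest statistically acceptable fraction (1/3) of the epoch, m as the
smallest dimension that separates fractionation levels without producing
undefined values.  `sweep_m` reproduces that selection procedure on any
labelled dataset, scoring each m by the Kruskal–Wallis H statistic of the
per-record medians across classes, subject to zero undefined epochs.

**Lag selection.**  `first_mi_minimum` estimates the time-delayed mutual
information from a 16-bin equal-width joint histogram at lags 1..50 and
returns the center of the first valley: the first strict local minimum,
expanded to the surrounding plateau of lags within 5% of the curve's
range above it.  The expansion matters because binned MI curves of
strongly periodic signals bottom out in a flat valley (for a sinusoid the
valley is symmetric about the quarter period, which is the meaningful
delay); without it the estimator returns the valley's left edge, which is
an artifact of estimator noise.  If no strict local minimum exists the
argmin is returned with a `fallback` flag.  The lag is a per-dataset
global, not re-selected per epoch; the shipped default (8 samples) is
used unless selection is requested (`--select-tau`).

## Surrogate test

One iaaFT surrogate alternates two projections until the rank permutation
reaches a fixed point (or the amplitude-spectrum discrepancy drops below
5% relative L2, or 1000 iterations): impose the original Fourier
amplitude spectrum on the candidate's phases, then rank-remap onto the
original sample values.  Ending on the rank-remap makes the amplitude
distribution *exactly* equal to the original's (sorted arrays identical);
the spectrum is matched approximately.  The distribution-exact variant is
the right one here because CGCD depends on amplitude geometry.

The test computes the median CGCD of the original and of 40 surrogates
and rejects linearity one-sided when the original ranks first (below all
surrogates), p = 1/41 ≈ 0.024 — the empirical direction: phase
randomization spreads the localized deflections and *raises* apparent
complexity.  A two-sided mode (reject at either extreme rank) is
available by flag.

One design point required care: the wavelet denoiser is a nonlinear map,
so surrogates built from the *denoised* series test a null the input
never satisfied — pure Gaussian noise was rejected in 100% of trials in
that configuration, because the rank test correctly detected the
denoiser's imprint.  Surrogates are therefore generated from the
normalized, low-pass-filtered series, and the denoiser is applied
identically to the original and to every surrogate before epoching.
Under the linear null both branches then remain exchangeable; measured
type-I error on white Gaussian noise is ≈0/100 to a few/100 across seed
sweeps, at or below the nominal 2.4%.

Organized (Type I) records do not always reject: their median CGCD sits
in the lower ranks of the ensemble but not necessarily strictly below it.
This matches the qualitative expectation that *most* — not all — AF
recordings test nonlinear, with the most organized ones closest to the
linear null.

## Classification

The feature is one ordered scalar (the record's median CGCD), so the
classifier is a pair of cuts: value < T1 → Type I, < T2 → Type II,
≥ T2 → Type III, with boundary values going to the upper class.  It is
fitted by exhaustive search over candidate cut pairs — midpoints between
consecutive sorted unique values plus one sentinel on each side (so a cut
may predict an empty class, which matters for overlapping training sets)
— minimizing training misclassifications, with the largest summed gap
(maximal margin) as tie-break and the smaller cut pair as the final
deterministic tie-break.  This is equivalent to a depth-limited decision
tree with two splits on one feature, but exactly reproducible and
testable against a brute-force oracle.  Cross-validation is seeded
stratified k-fold; when k exceeds the smallest class count (10 folds over
8 records per class) strict stratification is impossible and a plain
seeded shuffled k-fold is used, re-drawn (perturbed seed, up to 100
attempts) if any training part lacks a class.  The shipped reference
thresholds T1 = 1.3880, T2 = 2.0326 were learned on a full clinical
database and are defaults for clinical use, not quantities this package
reproduces.

One-vs-all ROC uses the raw median as score for Type III (higher = more
fractionated) and the negated median for Type I; AUC is trapezoidal and
the reported operating point maximizes the Youden index.  Group
comparisons report Shapiro–Wilk per group (skipped below n = 3), Levene
across groups, Kruskal–Wallis omnibus (Mann–Whitney when only two
groups), and pairwise Mann–Whitney with Bonferroni factor equal to the
number of pairwise tests actually run.

**Type IV detection** classifies every defined 1-s epoch with the
thresholds; if Type III and Type I-or-II epochs coexist the record is
Type IV, otherwise the median of the defined epochs is classified
directly.  A caveat the user should know: single-epoch CGCD is a noisy
estimate, so a uniform record whose epoch values straddle T2 can
false-trigger the alternation rule.  With the synthetic defaults,
record-level medians separate the classes with wide margins but
epoch-level distributions of Types II and III overlap near any T2, so
the segment-wise rule is best reserved for records where alternation is
actually suspected — which is how it is used in the Group-3 experiment
design, where its detection rate is 20/20.

## Synthetic generator

The generator produces what the estimator needs to be tested on:
single-channel bipolar EGM look-alikes with controlled class morphology,
not biophysical simulations.  Activations are biphasic
difference-of-Gaussians wavelets (σ = width/5, unit nominal peak, exact
zero outside ±width); absolute scale is irrelevant downstream.  Per
class:

* **Type I**: one quasi-regular train (cycle length ~ N(170 ms, 8%),
  floored at twice the wavelet width), white baseline noise (SD 0.02)
  plus a slow 1–15 Hz residual baseline activity (SD 0.03) standing in
  for the low-amplitude far-field and motion components organized
  recordings retain.
* **Type II**: Type I (bit-identical for the same seed when the
  perturbation SD is zero) plus band-limited 2–20 Hz colored noise
  (SD 0.30) — the atrial fibrillatory-wave band — perturbing the
  baseline while activations remain the dominant peaks.
* **Type III**: five independently timed trains with short cycle lengths
  (70–120 ms, the CFAE regime), randomized amplitudes (0.3–1.0) and
  widths (±30%), peak-normalized, plus a 40–250 Hz continuous-activity
  floor (SD 0.10) modelling the summed far-field of simultaneous
  wavefronts, so no isoelectric gap of ≥50 ms survives.
* **Type IV**: per-tag segments concatenated with a 10 ms cross-taper at
  junctions (fade-out/fade-in, avoiding step discontinuities that would
  inject broadband energy); ground-truth tags are stored in the record
  metadata.

All draws derive from per-purpose child streams of the record seed, so
datasets are bit-reproducible and limit cases (e.g. zero perturbation)
degenerate exactly.

**Calibration.**  The class taxonomy is visual, so no quantitative
morphology parameters exist to copy; the noise SDs and bands above were
calibrated once, against the behaviour the index is defined by: median
CGCD must order Type I < Type II < Type III for every seed, with
record-level margins wide enough that the two-cut classifier
cross-validates perfectly on 24-record datasets for arbitrary master
seeds (checked over 30 datasets), and class means near the reported
clinical operating range (here ≈0.8 / ≈1.7 / ≈2.9).  The bands matter
more than the SDs: slow smooth wander embeds as a low-dimensional curve
(pulling Type I toward CGCD ≈ 1), the 2–20 Hz fibrillatory band reads
≈1.7 at these settings, and broadband activity approaches the embedding
dimension.  After calibration the defaults are fixed; they are the study
conditions, not fitting knobs.

**What the generator does not emulate** — and hence what passing tests
do not show about clinical data: wave propagation and rotor dynamics,
electrode contact and motion artifacts, ventricular far-field
contamination, respiration drift, mains interference, inter-patient
amplitude and cycle-length distributions, and the borderline morphologies
that made 15 of 119 clinical records controversial to human readers.
Synthetic classes are cleaner and better separated than clinical ones;
perfect synthetic classification does not predict the mid-80s% accuracy
regime reported on full clinical databases.

## Problem sizes

Default records are 10 s at 1 kHz (10 epochs).  The canned experiment
designs use 24 records (8 per class) for threshold fitting and ROC, 20
alternating records for Type IV detection, and a configurable-count
design for overlap studies.  The surrogate type-I control in the test
suite uses 2-s Gaussian records over 100 seeds — long enough for two
epochs per record, chosen to keep the full suite fast.  The acceptance
script (`scripts/acceptance.py --seed N --out f.json`) regenerates
everything it reports from the seed at these sizes.

## Known limitations

* CGCD values depend on (m, τ, Nref, δ) jointly; values computed under
  different settings are not comparable, and the shipped clinical
  thresholds only apply at the default operating point.
* Epoch-level CGCD variance is substantial (the price of 1-s windows);
  conclusions should rest on record medians or on explicit alternation
  hypotheses, as discussed above.
* The iaaFT spectrum match is approximate (≤5% relative L2 by default);
  the amplitude distribution is exact.  The converse variant (exact
  spectrum, approximate distribution) is not implemented.
* `first_mi_minimum`'s histogram estimator is adequate at 10⁴ samples
  but biased for much shorter series; τ selection should use whole
  records, not epochs.
* File I/O covers the package's own text format only; proprietary
  acquisition-system exports must be converted externally.
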