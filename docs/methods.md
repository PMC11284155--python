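# Methods

This note records the scientific and numerical choices behind the package:
what the pipeline assumes, what the synthetic generator does and does not
emulate, and where a genuinely open design point was settled.

## The prediction problem

Seizure prediction presumes a preictal state: a window of altered brain
dynamics preceding onset. An alert device splits the window into the
seizure prediction horizon (SPH, here 10 min — the lead time an alarm must
give for intervention) and the seizure occurrence period (SOP — the span in
which the seizure is then expected). An alarm at time *t* is correct iff an
onset falls in [t+SPH, t+SPH+SOP]; a seizure arriving during the SPH counts
against the alarm. The positive class for training spans the full SPH+SOP
before onset, capped at one hour, and the SOP is a per-patient parameter
selected on training seizures from the 10–55 min grid in 5-min steps.

Two evaluation regimes coexist in the literature because datasets differ in
what they release. Continuous, annotated recordings support the alarm view
(sensitivity over seizures, false alarms per interictal hour). Clip-based
releases without absolute timestamps only support the sample view
(window-level sensitivity/specificity/AUC). The package implements both and
keeps them structurally separate: a segmented run carries no alarm metrics
at all.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a physiological
model. Each channel's background is 1/f-shaped Gaussian noise (exponent 1,
standard deviation 10 µV) plus a random-phase sinusoid at 9–11 Hz with
amplitude 8 µV. The oscillator matters: it gives the spectral-edge and
band-ratio features a realistic non-flat spectrum, and yields a baseline
alpha relative power near 0.5 rather than the degenerate flat-spectrum
value. During the configured preictal window before each onset, power in a
chosen band is multiplied by a factor ramping linearly from 1 to the effect
size: band-limited Gaussian noise with local variance (m(t)−1)·P_band is
added, where P_band is the channel's measured baseline power in that band.
With effect size 1 the preictal and interictal windows share one generating
distribution exactly (the null patient). The injection filter is applied
causally; only the band's power content matters, and measurement and
injection use the same filter so their bandwidths match.

Deliberately not modeled: seizure morphology (ictal spans are simply
excluded by a 120 s post-onset blackout), artifacts (eye blink, EMG),
postictal suppression, circadian structure, and channel covariance beyond
independent backgrounds. Passing tests therefore demonstrate that the
pipeline recovers a band-power signature of known size and duration under
clean conditions — not that it would perform comparably on clinical EEG,
where published results with this same pipeline family are far more modest.

Desk-scale defaults: the clinical independent-seizure rule (≥4.5 h between
onsets) is a configurable parameter with a 1 h default floor, and the study
patients used by the tests and the acceptance script have 6 seizures 2 h
apart (≈11 h of recording, 2 channels), the smallest layout that leaves
clean room for the largest SOP candidate (55 min) plus the 1 h train/test
cut. The recovery experiment injects its signature over SOP+SPH = 40 min:
the labeled span always includes both periods, so a signature spanning
"SOP_true + SPH" is the configuration whose optimal label span corresponds
to SOP_true = 30 min. A signature of bare length L would instead be
recovered as SOP ≈ L − SPH, by the same argument.

## Feature set

The 59-feature decomposition is: 8 relative band powers + 36 pairwise
ratios over 9 bands (the 8 sub-bands plus broadband gamma 30–128 Hz) +
SEF50 + cumulative power at the edge + 4 moments + 3 Hjörth + decorrelation
time + 5 wavelet detail energies. The exact composition of the classic
59-feature set lives in prior work and is not fully recoverable; this
reconstruction covers every named family and totals exactly 59. The
registry is an ordered configuration object, so an alternative
decomposition can be swapped without code change.

Numerical conventions, chosen so closed-form oracles are exact and
documented here because tests depend on them:

* PSD: Welch, 1-s Hann segments, 50% overlap, no detrending (the 0 Hz bin
  never enters a band; the integration floor is 0.5 Hz, ceiling 128 Hz).
  Band masks are half-open [low, high), with the Nyquist bin folded into
  the top band. The mains gaps 47–53 and 97–103 Hz stay in the denominator
  of relative power but in no numerator, so the eight relative powers sum
  to ≤ 1 and no separate notch filter is needed.
* Ratios use one direction only (fixed band order) with an ε = 1e−12 guard.
* SEF50 is the smallest frequency with cumulative power ≥ 50% of total;
  "power at the edge" is that cumulative power in absolute units. All-zero
  windows return zero powers and the 0.5 Hz floor, and are flagged.
* Skewness and kurtosis use biased moment estimators, kurtosis in the
  Pearson convention (Gaussian → 3).
* Hjörth mobility/complexity use unscaled first differences, so a unit
  sinusoid of frequency f has mobility 2·sin(πf/fs) exactly.
* The autocorrelation is computed circularly via the FFT (exact cosines for
  whole-cycle sinusoids); decorrelation time is the first integer lag at
  which it is ≤ 0 to numerical precision (tolerance 1e−10), reported in
  seconds; if no crossing occurs within half the window, the window length
  is returned and flagged. Zero-variance windows return 0 for all
  scale-free features, with a flag.
* DWT: db4, 5 levels, periodization boundaries — the transform stays
  orthogonal, making the energy-conservation test exact to rounding.

## Training and model selection

Features are ranked by the absolute two-sample Welch t statistic on the
z-scored training windows; ties break by column index, and constant columns
(detected with a scale-relative tolerance, since float roundoff leaves them
with ~1e−29 variance rather than zero) rank last and are excluded by the
z-score transform. The ranking method and the feature-count grid
{5, 10, 20, 40} are reconstructions: the selection mechanism behind "the
optimal number of features" is not specified in the literature this
pipeline follows, so both are configuration.

Cross-validation folds are seizure-wise in the continuous regime: windows
are attributed to the block ending at each training seizure's
onset+blackout, each fold holds one block out, and the SS×SP objective is
averaged over folds. Ties on the grid prefer the smallest SOP, then the
smallest feature count — the less complex model. In the segmented regime
(labels fixed by files) folds are three seeded 70/30 file re-splits and
only the feature count is searched.

The classifier is logistic regression with inverse-frequency class weights
and no regularization beyond numerical jitter (L2 with C = 1e6, which also
keeps the solver stable on separable data). The chronological split places
the cut 60 min after the last training seizure's onset so no test preictal
window leaks into training; seizures whose preictal span would cross the
recording start are truncated rather than discarded.

## Alarms

Firing Power uses zero-padded warm-up (early values ramp from 0, so the
warm-up cannot raise alarms — the conservative choice; normalizing by the
available history would inflate early values). Alarm semantics: upward
crossing of the 0.7 threshold plus a refractory period of one preictal
duration; after the refractory period expires, a still-elevated series
retriggers immediately (sustained-alert device behaviour). Both halves of
that rule are flags, since devices differ. For segmented data the Firing
Power would reset at file boundaries; the segmented pipeline does not build
alarms at all.

The FPR/h denominator is interictal time: test duration minus the union of
per-seizure preictal spans and ictal+blackout spans. Refractory spans are
not excluded (slightly inflating FPR — conservative). A full-duration
denominator is available as a flag. A single alarm whose occurrence window
contains two onsets counts both as predicted (configurable; the refractory
period makes it rare).

## Surrogate validation

The alarm-view surrogate test redraws the onset times uniformly over the
admissible interictal span (pairwise separation ≥ SOP+SPH; by default also
outside a ±(SOP+SPH) zone around the real onsets, so surrogates cannot
score by proximity to true seizures) and re-scores the fixed alarm series
30 times. When seizures are dense enough that the exclusion zones leave no
room to place the surrogates — common at desk scale with a large selected
SOP — the test falls back to unconstrained interictal placement with a
warning rather than failing. The sample-view surrogate circularly shifts the label sequence by
30 distinct nonzero offsets, preserving label run-lengths.

The decision rule is the empirical rank test,
p = (1 + #{surrogate ≥ observed})/31, validated iff p < 0.05 and the
observed value exceeds the surrogate mean — equivalently, iff the observed
sensitivity strictly beats all 30 surrogates (p = 1/31 ≈ 0.032). A
one-sided one-sample t-test of the surrogates against the observed value is
available as an option but is not the default: that test treats the
observed statistic as a constant, and under the null — where the observed
value fluctuates exactly like one more surrogate — its effective statistic
is inflated by roughly √n_surrogates, producing false-positive rates above
30% in simulation. The rank rule is exact under exchangeability; its
rejection rate is bounded by 1/31 and reduced further by ties when the
sensitivity takes few values. The null calibration therefore uses 20
seizures over 48 h of monitoring with a ~0.3/h random-alarm rate (the scale
of clinically reported false-alarm rates), where the sensitivity statistic
is fine-grained enough for the empirical rate to approach its 3.2% ceiling;
exclusion zones are disabled there because exchangeability requires the
real onsets and the surrogates to follow the same law.

## Problem sizes

Tests and the acceptance script use: 20 strong-effect patients for
parameter recovery, 6 null patients, 10 (tests) / 3 (script)
segmented-regime patients, 200 null replications for the surrogate
calibration, 1000 random sequences for the Firing Power oracle, and 500
random instances for the alarm-matching oracle. One strong-effect patient
(11 h, 2 channels) runs the full pipeline in ~20 s on one CPU.

## Known limitations

* The synthetic preictal signature is a stationary-in-band power ramp; real
  preictal dynamics, if present, are nonstationary and patient-specific.
* CNN-based artifact removal used for some clinical datasets is out of
  scope; the filter path here is the one used for the other datasets.
* The exact 59-feature composition and the feature-selection mechanism are
  reconstructions (flagged above).
* The sample-view surrogate mechanism for clip-based data is a
  reconstruction (circular label shifts); the literature describes the
  onset-randomization surrogate only for the alarm view.
* No probability calibration, ensembling, or nonlinear/bivariate features.
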