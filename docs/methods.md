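# Methods

This note records the scientific and numerical choices behind `hammersound`:
what the pipeline computes, what the synthetic cohorts do and do not emulate,
and where genuinely open design decisions were resolved.

## Problem and data model

One *operation* is one THA surgery: the femoral canal is rasped with an
ascending sequence of rasp sizes, each seated by several mallet blows, until
the surgeon judges the final size seated.  The raw datum is a mono recording
of the whole rasping phase plus a human-curation sidecar listing, for each
automatically detectable onset, whether it is a genuine hammer strike (and at
which rasp size), a non-strike sound, or a strike overlapped by conversation
or other noise.  The unit of analysis is a single strike; the classification
target is whether a strike was made during final-size rasping.

The canonical sampling convention is 44.1 kHz, 16-bit mono.  At that rate the
4096-sample analysis window spans 0.0929 s and the Nyquist frequency is
22.05 kHz; other input rates are polyphase-resampled on ingest.

## Signal extraction

* **Onset envelope.** Half-wave-rectified spectral flux over rectangular
  (untapered) frames of 1024 samples with hop 256: the envelope value at
  frame *k* is the summed positive magnitude increment from frame *k−1*.
  Rectangular frames are used because a taper attenuates a transient
  entering at the frame edge, which biases the flux peak late.  The first
  frame has no predecessor and its flux is defined as 0, so an onset inside
  the first 23 ms of a recording is not detectable — irrelevant in practice
  since recordings begin before the first strike.  Each flux value is
  assigned the time at which its frame's novel content begins
  (`k·hop + frame − hop` samples), which places the flux peak within one hop
  of the physical onset.
* **Peak picking.** Peaks must exceed a moving median plus
  `k × 1.4826 × MAD` (a robust z-score with `k = 4` over a ~1 s context)
  *and* 10% of the envelope maximum.  The absolute floor matters in long
  quiet gaps between rasp sizes, where the local MAD band is tight enough
  that noise-flux excursions would otherwise cross it; impacts dominate the
  envelope by roughly an order of magnitude at the SNRs of interest, so the
  floor costs no sensitivity.  Onsets closer than 150 ms are greedily pruned
  keeping the larger peak (strikes arrive at ≳ 350 ms spacing; ring-down
  lasts ≲ 150 ms).
* **Refinement.** Envelope peaks have hop-level (5.8 ms) resolution; each is
  refined to the first sample whose absolute amplitude exceeds 25% of the
  local maximum in a frame-sized search window.  On simulated strikes this
  lands within ~0.3 ms of the true onset.
* **Curation.** Detections within ±10 ms of an annotated kept onset inherit
  its size label; unmatched detections and annotated non-strikes are
  `deleted`; a kept annotation with no detection is synthesised from the
  annotated time (the human annotation is ground truth).  Any kept strike
  whose 4096-sample window intersects an annotated noise interval becomes
  `excluded_overlap`.  The exclusion applies to *every* overlapped strike,
  not only final-size ones — the conservative reading, since a contaminated
  window is contaminated regardless of its label.  Only `kept` strikes are
  ever featurized; windows cut short by the end of the recording are
  zero-padded (preserving the `R^4096` contract) with the padding fraction
  logged.

## Features

The power spectrum is the squared magnitude of the plain 4096-point DFT —
no taper (the transient starts at the window start, and a taper would
suppress exactly the attack) and no normalisation.  The full 4096-bin
spectrum is Hermitian-redundant for real input, so model features use the
2049 one-sided bins (bin width ≈ 10.77 Hz), optionally restricted to a band
`[f_lo, f_hi]` below Nyquist.  The default model input is
`ln(power + 1e-12)`: spectra span many decades and raw power makes the
logistic-regression problem badly conditioned.  Raw power is retained as an
option (`transform=raw_power`), since the original analysis does not state a
transform; the choice is exposed, not hidden.

## Datasets

Within one operation, strikes at the final rasped size are positive;
negative definition A takes strikes at the operation's *minimum* rasped size
(the first entry of its rasp sequence, not a catalogue-global minimum);
negative definition B takes strikes at *all* undersized sizes, which
includes the minimum — so every operation's negative-A set is a subset of
its negative-B set.  Dataset A = (one stem design, negative A),
B = (same filter, negative B), C = (all stem designs, negative B).
Operations flagged for early post-operative stem subsidence are excluded
before assembly, mirroring the clinical exclusion criterion.  Operations
whose rasp sequence has a single size contribute positives only.

## Models

All six configurations use L2-regularised logistic regression with inverse
regularisation strength `C = 0.1` (larger C = weaker penalty, the standard
convention), solved by lbfgs with tolerance 1e-8 and an iteration cap of
1e5; non-convergence is an error, not a warning.  Truncated SVD (models B,
D, F) keeps the top 10 right singular vectors without centering; if the
training block has lower rank the basis truncates to the rank with a
warning.

Ensembles (C–F) build one weak learner per training operation (`K−1`
learners in a leave-one-out fold).  Models C/D partition the pooled training
examples into `K−1` random, near-equal, class-stratified subdata and train
each learner on exactly one subdatum; stratification minimises skipped
single-class learners, which the original description does not address.
Models E/F train one learner per operation.  In D and F the tSVD is fit per
weak learner on that learner's own training subset, keeping learners
independent; a global-tSVD variant is available (`tsvd_scope="global"`) for
sensitivity analysis.  Every weak learner standardises features on its own
training subset by default (`standardize=False` gives the literal unscaled
variant).  Single-class subsets are skipped with a warning; a model whose
subsets are all single-class is an error.  Ensemble prediction is the
arithmetic mean of learner probabilities.

The random partition is made order-invariant by canonically ordering
examples with a seeded random projection of their feature rows before the
seeded shuffle, so training does not depend on row order.

## Evaluation

Exhaustive leave-one-operation-out CV: one fold per operation, every strike
of the held-out operation is test data.  (Describing the protocol as random
selection of a test operation is only consistent with a median over folds if
every operation is held out once, so the exhaustive reading is used.)
Per-fold ROC-AUC uses the Mann–Whitney form, ties counted one half.  Folds
whose held-out operation has a single class have no defined AUC; they are
recorded as undefined and excluded from the median (imputing them would bias
it), with both the total and the used fold counts reported.  Medians over an
even number of folds are the mean of the middle two values.

## Synthetic cohorts

The generator emulates the structure the analysis depends on, not the
physics of bone–implant contact:

* **Strike model.** Three exponentially damped sinusoids at frequency ratios
  1 : 2.7 : 6.3 with amplitudes 1 : 0.5 : 0.25 and ring-down constants
  30/12/6 ms, 150 ms long, peak-normalised; per-strike lognormal jitter on
  mode frequencies (σ = 1%) and amplitudes (σ = 25%), uniform random phases.
  The ratios put the upper modes in the few-kHz region where impact energy
  has been reported to be prominent (~1 kHz and ~7 kHz for a ~1–2 kHz
  fundamental).
* **Seating effect.** Modal frequencies and ring-down constants scale by
  `1 + β·s`, where the seating fraction `s` rises linearly over the rasp
  stages from 0 (first size) to 1 (final size).  `β = 0` makes the waveform
  distribution identical across classes — an exact pipeline null.  The real
  effect size and even its sign are unknown (the source analysis reports
  AUCs, not spectra); β is a simulation parameter, default 0.4, never
  claimed to match surgery.
* **Heterogeneity.** Each operation draws a base fundamental from a
  lognormal with median 2 kHz and σ = 0.25, scaled by a stem-design
  multiplier (Accolade2 1.00, TaperlocCM 1.15, Twinsys 0.78, Optimys 1.45;
  short and long stem designs ring far from the taper-wedge reference).
  This is what makes the mixed-stem dataset C hardest and rewards
  operation-wise ensembles, reproducing the qualitative orderings.
* **Session layout.** 3–5 rasp sizes per operation (sizes occasionally
  skipped), 5–10 strikes per size at 0.35–0.7 s spacing, 1.2–2 s gaps
  between sizes.  Ground-truth strikes are always ≥ 200 ms apart.
* **Contamination.** Stationary Gaussian background noise calibrated to the
  configured SNR (default 20 dB, strike RMS over its 150 ms vs noise RMS);
  Poisson monitor beeps (sharp 2.4–3.2 kHz transients the detector finds and
  the annotation deletes); per-strike Bernoulli conversation bursts
  (band-limited 100–1000 Hz noise, 0.4–0.8 s) recorded as noise intervals.
  Contaminated strikes get extra clearance so a burst flags only its own
  strike.
* **Determinism.** All randomness flows from `SimConfig.seed` through
  spawned substreams, one per operation, so cohorts are bit-identical across
  runs and operations are replayable in isolation.

What the generator does **not** emulate: real bone/implant mechanics,
speech (band-limited noise suffices to test exclusion logic), nonstationary
theatre noise, recording-chain nonlinearity, or operator technique drift.
Passing tests therefore demonstrate that the pipeline recovers the intended
structure when it exists, and stays at chance when it does not — they say
nothing about effect sizes in real surgery.

## Problem sizes used in the test suite

The end-to-end properties run on 20-operation cohorts (three seeds each) for
the null-calibration, ordering and leakage checks, 12-operation cohorts for
the effect-size monotonicity sweep (β ∈ {0, 0.1, 0.2, 0.4}, model E,
dataset A), and 10 recordings for extraction fidelity.  These sizes give
stable medians (order-of-0.02 seed-to-seed spread on mean-of-median AUCs)
while keeping the suite fast; the worked-example fixture is a single
operation with the strike counts fixed by construction.

## Known limitations

* The onset detector is tuned for impulsive metallic impacts against a
  quasi-stationary background; highly nonstationary noise would need a
  different threshold model.
* The worked-example strike counts pin the labeling arithmetic, but
  per-size strike counts in real surgeries vary far more than the generator's
  5–10 range.
* ROC-AUC medians on small cohorts are noisy; no confidence intervals or
  between-model significance tests are provided (medians only, matching the
  reporting of the analysis this package operationalises).
* `fit_tsvd` uses ARPACK for k < min(n, d) and a full SVD otherwise; for the
  matrix sizes here (≤ a few hundred × 2049) both are exact to working
  precision.
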