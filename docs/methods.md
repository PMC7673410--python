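# Methods

This note documents the statistical and numerical choices behind
`stagefree`: what each stage computes, where the design was genuinely
open, what the synthetic generator does and does not emulate, and the
known limits of what the tests demonstrate.

## Preprocessing

Recordings (10 channels, linked-mastoid referenced, 250 Hz) are band-pass
filtered 0.5–50 Hz with a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`).  Zero-phase filtering has no group delay, so 5-s epoch
boundaries are identical before and after filtering.  The filter's
attenuation of mains interference at 60 Hz is 19.1 dB (40·log10|H(60)|);
this is adequate because a 0.5–50 Hz cohort should be notch-filtered at
acquisition if mains contamination is severe.

Epochs are non-overlapping 5-s windows; a trailing partial epoch is
discarded.  Per-epoch spectra come from a single Hann-tapered FFT per
epoch (0.2 Hz bins), and "band power" means the mean one-sided PSD over
the half-open band [low, high).  Both rejection rules are ratios of such
powers, so the PSD normalisation cancels; the mean-vs-total choice only
matters for the white-noise diagnostic (a flat spectrum gives equal
mean-PSD band power in every band).

Artifact rules, applied per channel, EMG rule first:

- **EMG**: reject epoch *e* iff its 26–50 Hz power strictly exceeds 4× the
  moving median over a 36-epoch (3-min) window centred on *e*.  The window
  is truncated at recording edges rather than padded (no fabricated data).
  Whether the original 3-min window was centred or trailing is unknowable
  from the description; centred is the symmetric choice and is flagged
  here deliberately.
- **Movement**: reject epoch *e* iff its 4–50 Hz power strictly exceeds 6×
  the whole-night median of that channel, with the median computed over
  *all* epochs (including EMG-rejected ones).  This makes the rule
  idempotent and order-insensitive with respect to the EMG rule.

"Exceeds" is read as strictly greater: an epoch at exactly the threshold
is kept.

## Features

- **LP** is the mean of the *log* band power over kept epochs
  (mean-of-log, not log-of-mean), natural log throughout.  The log base
  only shifts LP by a constant factor but changes LCV, so it is fixed.
- **LCV** is sample SD (n−1) over mean of the same log-power series.
- **W** (weighted phase lag index) pools the imaginary cross-spectrum over
  all jointly-kept epochs and all frequency bins inside the band into one
  ratio of sums, rather than averaging per-bin ratios: the estimator is
  defined as a ratio of expectations and pooling maximises the effective
  sample count at 5-s resolution.  W is symmetric, scale-invariant, and
  returns a missing value when the denominator is zero (no imaginary
  energy).

Band edges are half-open [low, high): the 10 Hz bin belongs to Hα.  With
a Hann taper, a pure on-bin sinusoid still leaks ≈ a quarter of its peak
amplitude into each adjacent bin, so band-assignment is dominance (about
5× power), not exclusivity.

## Conditioning (train-derived, all-applied)

Synchrony features are replaced by ln(max(W, 1e-6)); the floor keeps hard
zeros finite and sits below any attainable WPLI at realistic epoch
counts.  Night consistency is Lin's concordance correlation coefficient
across training subjects (night-1 vector vs night-2 vector; population-
variance form); features with CCC > 0.7 are retained.  Age screening uses
Pearson's r on control training observations, both nights pooled, p from
the exact t transform, no multiplicity correction (a deliberate mirror of
the per-feature p < 0.05 rule); significant features are corrected for
*all* subjects by subtracting b·(age − ā) with ā the control-train mean
age — centring preserves the feature scale so downstream thresholds stay
interpretable.  Every parameter of this stage is estimated on training
rows only, so deleting test rows reproduces identical retained sets and
slopes (tested).

## Univariate selection

AUC is the Mann–Whitney statistic (ties ½).  Because AUC is
direction-sensitive, each feature's orientation is fixed from training
night 1 (sign making AUC ≥ 0.5) and reused for night 2, the concatenated
vector and the classifier — flipping per night would bias selection.
Note the consequence: the night-1 test becomes two-sided (≈5% null rate)
while night 2 remains one-sided given the orientation.  CIs are DeLong
(midrank structural components); a seeded stratified bootstrap is
available.  Selection requires the CI lower bound > 0.5 on *each* night.
Concatenated-night AUCs double the observations per subject; they are
used for ranking only, never for selection CIs (anticonservative under
within-subject dependence).

With realistic night-to-night feature stability (ρ ≈ 0.85), the two
nightly statistics of a *null* feature are strongly correlated, so the
joint pass rate is ≈3%, not the ≈0.06–2.5% that independent nights would
give.  On 780 features this admits ~20 false positives — an inherent
property of the two-night guard, not an implementation artifact.

## Clustering

Székely's sample distance correlation (biased V-statistic; the unbiased
variant is a config option) over the concatenated training vectors;
agglomerative clustering on dissimilarity 1 − dCor with complete linkage,
cut just below 0.3 so that every within-cluster pair has dCor strictly
above 0.7 — complete linkage is the only standard linkage that guarantees
this pairwise property, which is asserted post hoc.  Cluster
representatives are the members with the highest concatenated AUC, ties
broken lexicographically for determinism.

## Classifier

Logistic regression on training-standardised features with a weak L2
ridge (penalty 1/(100·n) on the summed log-likelihood), deterministic and
convergent under perfect separation.  RFE drops the feature with the
smallest |standardised coefficient| at each step; the ranking fit uses a
moderate ridge (C = 1), because a near-unpenalised fit with ~19 features
on ~94 quasi-duplicated rows is close to separation and its coefficient
magnitudes are too noisy to rank by.

**Stopping rule.**  The model size along the elimination path is chosen
by BIC by default: in-sample deviance rescaled to the subject level
(concatenated nights double-count rows correlated ≈0.85 within subject,
so deviance is multiplied by n_subjects/n_rows) plus log(n_subjects) per
coefficient.  Two alternatives are kept as options: `ebic` (adds
2γ·log(p) per coefficient, for stricter control with many candidates) and
`cv_1se` (smallest size within one standard error of the best mean
six-fold CV AUC).  The CV-based rule is attractive on paper but unstable
at cohort scale: six folds of ~8 subjects give fold AUCs with SD ≈ 0.05,
the "best" size is max-biased, and the overfitting component of the noise
is shared across folds, so neither widening the band, repeating the CV,
nor paired fold comparisons make the size decision reliable (support
recovery ~15–25% in simulations where BIC achieves >95% at adequate n).
The six-fold CV AUC curve is still computed along the path for
diagnostics.  Folds are stratified by group and keep both nights of a
subject together — the conservative choice against within-subject
leakage.

Thresholds: the largest probability cutoff whose training sensitivity
(predict positive when p ≥ cutoff) meets each target (0.80, 0.90); the
achieved sensitivity is stored with the cutoff.  Evaluation reports
sensitivity, specificity, AUC with DeLong CI, and the
prevalence-adjusted PPV `sens·π/(sens·π + (1−spec)(1−π))` at π = 0.15
(the assumed prevalence among combat-exposed Veteran men, overridable);
values are rounded to two decimals only at the reporting layer.

## Synthetic cohorts

The signal tier builds each channel as a sum of 12 band-limited Gaussian
processes (4th-order Butterworth-filtered white noise) with a 1/f-like
amplitude profile (RMS ∝ fc^−0.6, ~30 µV·fc^−0.6).  Phase coupling adds a
shared band-limited source to both channels of four central pairs
(C4–P3, C4–F3, C3–P4, C3–F4) with a quarter-cycle delay at band centre,
which guarantees a nonzero imaginary cross-spectrum and hence WPLI
sensitivity; generated WPLI rises monotonically with the configured
coupling strength (tested).  Group structure: PTSD multiplies 1–4 Hz
amplitude by exp(effect·s/2) (effect −0.8 by default, s = 0.3 the
between-subject SD of log power) and coupling by exp(effect·s) in the
alpha and low-gamma bands.  Age tilts slow-band log power by −0.015 to
−0.02 per year.  A per-subject random effect shared across nights, with a
night-specific remainder sized by the target test–retest correlation
(0.85 by default), produces the two-night concordance.  Artifact epochs
(2% by default) receive either 26–50 Hz bursts on three random channels
(to be caught by the EMG rule) or 4–50 Hz broadband lurches on all
channels (movement rule).  Same config and seed ⇒ byte-identical output.

The feature-table tier emits the 780-column table directly from the
latent model `mu + effect·1[PTSD] + slope·(age − midpoint) + b_subject +
e_night` with Var(b) = ρ, Var(e) = 1 − ρ (unit total variance, so effects
are standardised and the between-night correlation is ρ).  Synchrony
columns are mapped through expit(0.8z − 1.5) so they land in (0, 1) as
the conditioning stage requires; the map is monotone, so rank-based
selection behaviour is unchanged, though the nonlinearity mildly
attenuates CCC and standardised effects on the transformed scale.
Synchrony group effects apply only to the four coupled pairs, mirroring
the signal tier.

Default cohort scale mirrors the study design: 31 PTSD / 47 control men
aged 24–51, two nights, with the first ceil(0.6·n) generated subjects
(proportionally interleaved by group) forming the training split —
a consecutive-subject split, not a random one.  Night duration defaults
to 600 s (120 epochs) so full-pipeline tests run in seconds; 8-h nights
are supported.  Per-feature effect sizes are free parameters of the
generator (the study's per-feature effects are not published in the main
text); defaults of ±0.8 SD were chosen once as a moderate, plausible
group difference.

What the generator does **not** emulate: sleep microstructure (spindles,
K-complexes, REM/NREM cycling), stage-dependent spectra, non-Gaussian
artifacts, electrode drift, or correlated noise across channels beyond
the explicit coupling.  Passing tests therefore demonstrate that the
pipeline's statistics behave correctly under the assumed data-generating
model, not that the published clinical effect sizes are reproducible.

## Support-recovery benchmark

`simulate_selection_table` generates the benchmark for the selection →
clustering → RFE funnel: all 780 features are iid unit-Gaussian
observation noise; three planted features (one delta log power, two
synchronies) add a ±1.5 SD group shift (per-night AUC ≈ 0.86).  With
60 PTSD / 90 control subjects the funnel returns exactly the planted set
in ≥80% of seeds (tested over 50 seeds).

Both design choices matter and are deliberate.  (i) *Null model*: iid
observation noise makes a null feature's two nightly statistics
independent, so the two-night rule controls false inclusion near the
product of its per-night rates.  Under subject-stable nulls
(ρ ≈ 0.85) — the realistic regime — the surviving nulls are precisely
those with genuine in-sample label associations, which no internal
criterion (CV, BIC, or otherwise) can distinguish from weak true effects;
exact support recovery is then information-limited at any cohort size.
(ii) *Cohort size*: at 47 training subjects even iid nulls leave BIC
near-saturated deviances; ~100 subjects is where recovery stabilises.
This is a known limitation of the workflow at the original cohort scale
and the reason the final-model feature list from any single ~50-subject
cohort should be read as one plausible minimal set, not as the unique
underlying support.

## Numerical conventions

- Missing values (zero kept epochs, zero WPLI denominator, undefined
  LCV) propagate as NaN and are logged, never silently imputed.
- Exact-threshold comparisons: rejection rules and the CCC/dCor cutoffs
  are strict (> not ≥); cluster cuts use 0.3 − 1e-12 so dCor exactly 0.7
  does not merge.
- Ties: AUC counts ties ½ (midranks); RFE coefficient ties drop the
  lexicographically later feature; representative ties pick the
  lexicographically earlier name.
- Seeds: a single top-level seed is expanded per stage via CRC-tagged
  `SeedSequence`s, so stage-level reruns are reproducible independently
  of Python hash randomisation.
- The feature-table cache in a run directory is keyed by a hash of the
  full cohort config; changing any config key invalidates it.
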