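# Methods

`csftriage` implements a computerized decision-support workflow for one
concrete clinical question: *given neuropsychology, MRI and APOE results,
which memory-clinic patients should receive CSF biomarker testing before a
diagnosis is settled?* The workflow has four statistical components — a
nonparametric multi-class classifier (the Disease State Index), a local
confidence estimate (probability of correct class), a stepwise
simulated-CSF test-ordering policy, and a synthetic cohort generator used
as the test bed. This note documents the model choices, the parameters
that matter, and the limits of what the synthetic experiments show.

## Cohort model and covariate correction

A cohort is a flat table: one row per patient with age, sex, an optional
clinical diagnosis (CONTROL = subjective cognitive decline, AD, FTD, VAD)
and 17 features in four modalities — seven neuropsychological scores
(MMSE, RAVLT learning/recall, TMT-A/B, animal fluency, NPI), six
MRI-derived markers (cMTA left/right, cGCA, WMH volume, AD similarity,
anterior–posterior index), APOE ε4 carriership, and three CSF analytes
(AB42, total tau, p-tau, pg/ml). Missing values are first-class: blank CSV
cells, NaN in memory; nothing is imputed anywhere in the pipeline.

Before classification every continuous feature is residualized against age
and sex: a least-squares model `value ~ age + sex` (sex coded 0 = male,
1 = female) is fitted on the *control group's* observed values, and each
observed value is replaced by its residual plus the control mean, keeping
the corrected value on the original measurement scale. Fitting on controls
rather than the pooled cohort prevents disease effects (which correlate
with age) from being absorbed into the correction; the trade-off is a
noisier fit, which is why at least 10 observed control values are required
per feature. Binary features are left untouched — a residualized 0/1
indicator has no meaning for the cutoff-counting machinery below.
Correction never changes the missingness pattern, and refitting on a
corrected cohort returns coefficients indistinguishable from zero.

## The Disease State Index

For a feature x and an ordered group pair (positive, negative), the
reference cohort defines an empirical fitness function

    f(x) = FN(x) / (FN(x) + FP(x)),

where FN(x) is the fraction of positive-group reference values strictly
below x and FP(x) the fraction of negative-group values at or above x —
the error rates incurred if the patient's own value were used as the
decision cutoff. f maps a raw measurement to graded evidence in [0, 1]
toward the positive group. Implementation details that the bare formula
leaves open, and how they are fixed here:

* **Orientation.** Whether high values indicate the positive group is
  decided per (feature, pair) by whichever direction attains the larger
  Youden index on the reference data, with ties (to within 1e-12, since
  float summation order can split an exact tie) going to
  higher-is-positive. Internally values are multiplied by the orientation
  so the positive group always tends higher.
* **Between-value behavior.** f is evaluated from the step counts at the
  query directly; no smoothing. On a perfectly separated stretch where
  FN + FP = 0 (between the highest negative and the lowest positive
  value), f is linearly interpolated from 0 to 1 across the gap, which
  keeps it defined and weakly monotone — and monotone it is, everywhere,
  because FN is nondecreasing and FP nonincreasing in the oriented value.
* **Degeneracy.** If every reference value of both groups is identical the
  function is flagged and pinned at the neutral value 0.5.

Each (feature, pair) also receives a relevance weight: the maximum of
sensitivity + specificity − 1 (Youden's J) over all cutoffs, in [0, 1].
Taking the maximum makes relevance a property of the feature rather than
of an arbitrary threshold. The pairwise DSI of a patient is then the
relevance-weighted mean of fitness values over the features *observed for
that patient* — missing features simply drop out, which is exactly
equivalent to excluding them from the feature subset. A feature with zero
relevance contributes nothing; if only zero-relevance evidence is
observed, the pairwise DSI is the neutral 0.5; if no feature at all is
observed for a pair, that pairwise value is undefined (never silently 0).

Six canonical pairs are fitted — (CONTROL, AD), (CONTROL, FTD),
(CONTROL, VAD), (AD, FTD), (AD, VAD), (VAD, FTD) — and reversed pairs are
derived as 1 − value rather than refitted, which enforces complement
symmetry exactly and halves the fitting cost. The total DSI of group g is
the unweighted mean of the three pairwise values with g as the positive
side (undefined pairs are skipped; a group with no defined pair is an
error). The predicted class is the argmax, with exact ties broken by the
fixed clinical order CONTROL < AD < FTD < VAD and flagged. The top value
d1, the runner-up d2 and the margin δ = d1 − d2 feed the confidence
estimate. Features enter a pair only with at least `min_ref = 5` observed
reference values in each group; below that the error rates are too
granular to mean anything.

Two model instances are used throughout: the *pre-CSF* model
(neuropsychology + MRI + APOE) and the *full* model (plus the three CSF
analytes).

## Probability of correct class (PCC)

A diagnosis suggested with d1 = 0.75 and δ = 0.08 deserves a different
level of trust than one with d1 = 0.95 and δ = 0.4. PCC estimates, for a
patient's (d1, δ), the probability that the suggested class is correct,
as the share of correctly classified reference cases with similar
coordinates:

1. Every reference case is classified by a DSI model refitted *without
   it* (leave-one-out; only the three pairs involving the case's own group
   change, so the refits are cheap), yielding a cloud of
   (d1, δ, correct?) points that is honest about generalization.
2. A query is standardized by the cloud's mean and SD per coordinate, and
   the k nearest points in Euclidean distance are selected, with ties at
   the k-th distance included so the answer is order-independent.
   k defaults to max(20, ⌈0.1 N⌉).
3. PCC is the fraction of selected points that were correctly classified.

This makes PCC a piecewise-constant, purely empirical function — no
parametric calibration model stands between the reference data and the
estimate. One PCC model is built per feature subset, because adding CSF
reshapes the (d1, δ) geometry.

Two properties are verified by simulation rather than assumed: on
no-signal cohorts (four balanced groups, one shared distribution) the mean
PCC sits at the four-class chance level 0.25; and on cohorts from the
default generator the binned calibration curve — estimated PCC vs realized
accuracy on an independent cohort of 2000 — agrees within 0.07 in every
decile bin with at least 50 patients, *pooled over five replicate
simulations*. The pooling is deliberate: a single bin of 50 patients has a
binomial standard error of about 0.07 by itself, so a per-replicate bound
at that tolerance would be a coin flip even for a perfect estimator.
Known limitation: in the sparse low-confidence corner of the cloud the
kNN share inherits a one-sided smoothing bias (neighborhoods reach into
better-populated, more accurate territory), so individual low PCC values
tend to be mildly optimistic; the pooled curve bounds this at a few
percentage points under the default conditions.

## Simulated CSF and the four ordering policies

The positive ("AD-like") CSF profile is the per-analyte median of the AD
group's corrected values; the negative ("normal") profile the medians of
the control group. Profiles always overwrite all three analytes together,
on the corrected scale — the simulation asks "what if this patient's CSF
looked typically AD-like / typically normal?", not "what if one analyte
moved?".

* **Scenario A (stepwise decision support).** Classify with the pre-CSF
  model; if PCC ≥ threshold (default 0.80) the patient is *directly
  diagnosed* (group 1), no CSF. Otherwise substitute each simulated
  profile and recompute PCC under the full models. If neither reaches the
  threshold, CSF is predicted unhelpful (group 2, untested). Otherwise
  CSF is ordered, the actual values are used, and the final PCC decides
  group 3 (diagnosed after CSF) vs group 4 (tested, still undiagnosed —
  the signature of mixed pathology). Which simulation fired is recorded
  as positive_only / negative_only / both.
* **Scenario B** uses the pre-CSF model for everyone (no testing),
  **scenario D** the full model for everyone (universal testing), and
  **scenario C** orders CSF for patients whose pre-CSF total DSI for AD
  exceeds 0.6 — an operationalization of published appropriate-use
  criteria. C's gate is computed from the pre-CSF model on purpose: the
  decision to order CSF cannot peek at CSF.

Structural consequences follow from the construction and are enforced by
tests: decision groups 1–4 partition the cohort; everyone diagnosed under
B is in group 1 under A; the share diagnosed is weakly decreasing in the
threshold for every scenario; B tests nobody, D everybody, and C exactly
the AUC-positive set. A patient selected for testing who lacks an actual
CSF value is a hard error in scenarios A and C; in D (testing is
unconditional) missing analytes are tolerated and the classifier falls
back on whatever is observed.

## The synthetic cohort generator

No patient data ship with the package; the generator is the test bed. Its
defaults reproduce the structure of a pooled three-center memory-clinic
cohort of 535: group sizes 139/286/82/28 (CONTROL/AD/FTD/VAD), per-group
feature means and SDs from the published baseline table (e.g. control
MMSE 28 ± 1, AD total tau 693 ± 405 pg/ml, VaD WMH 44.5 ± 29.6 ml), group
ages 62/67/63/70 ± 8/8/6/8 truncated to [40, 95], female shares
43/55/44/29 %, APOE ε4 carrier shares 42/65/34/48 %, and missingness from
1 % (MMSE) to 24 % (TMT-B), 12 % for APOE, completely at random. CSF and
MRI are never missing, mirroring the inclusion criterion that both had to
be available.

Continuous features are drawn from a Gaussian copula with a single
within-modality correlation (default 0.3) and truncated-normal marginals
on each feature's plausible range. A linear age trend of 0.03 feature-SD
per year (signed so performance declines and pathology accumulates with
age) is injected into every feature, anchored at the pooled mean age so
that the age/sex correction removes it identically in every group — a
group-specific anchor would smuggle an uncorrectable 0.1–0.2 SD group
signal into a nominally null cohort. `separation_scale` interpolates
every between-group difference (means linearly, SDs geometrically so they
stay positive, APOE frequencies with clipping) toward the size-weighted
pooled value: 1 reproduces the table, 0 collapses the groups onto one
distribution, 2 doubles the contrasts.

Because marginals are truncated, a sample group mean converges to the
truncated-normal expectation, not the configured location parameter; for
boundary-adjacent features (RAVLT recall in AD, 2 ± 2 with a floor at 0)
the difference exceeds sampling noise at any realistic n. Moment-recovery
tests therefore compare against truncated-normal theory (scipy), which
coincides with the configured values wherever truncation is negligible.

What passing on this test bed does *not* show: real cohorts have
mixed pathology, center effects, informative missingness and much richer
feature dependence than one correlation knob; classification is easier
here (holdout accuracy ≈ 0.9 with CSF) than in a real clinic, so absolute
shares of tested/diagnosed patients are not transportable. The structural
properties (partition, nesting, monotonicity, calibration methodology)
are what the synthetic experiments establish.

## Numerical and procedural choices

* Problem sizes in the shipped tests and the acceptance script: default
  535-person cohorts for model fitting, 2000-person evaluation cohorts
  for calibration (five replicates), 400 for null checks, 5000 per group
  for moment recovery, 240–320 for repeated-seed invariant checks —
  chosen to keep every Monte-Carlo bound several standard errors wide at
  single-CPU-friendly cost.
* Percentages in summary tables are rounded half-away-from-zero to whole
  percent. The two-sample proportion test uses the pooled-variance z and
  a Wald (unpooled) 95 % CI, no continuity correction; scenario arms are
  compared as independent samples for fidelity to the summary-table
  convention even though they share patients.
* Group comparisons across decision groups use one-way ANOVA for
  continuous variables and chi-square for categorical ones; groups with
  fewer than two usable observations report statistics but no p-value.
* Determinism: the generator is a pure function of its config (including
  the seed); model fitting and PCC queries contain no randomness, so
  every pipeline output is bit-reproducible.
* Serialization: covariate models, DSI models (reference values,
  orientation, relevance, plus breakpoints with fitness values for
  inspection) and PCC clouds round-trip through JSON; cohorts and
  outcome tables through CSV with blanks as missing.
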