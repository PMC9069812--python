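# Methods

## Scientific setting

Low-dose CT screening finds many indeterminate pulmonary nodules; most are
benign, but distinguishing the malignant ones non-invasively is hard.  One
blood-based aid is a seven-autoantibody (7-AAB) ELISA panel measuring serum
concentrations (U/ml) of antibodies against P53, PGP9.5, SOX2, GAGE7,
GBU4-5, MAGEA1 and CAGE.  The panel call is a disjunction: a patient is
panel-positive when **at least one** marker concentration is strictly above
its cutoff.  This package implements that rule, the diagnostic statistics
around it, and a small neural network that fuses the marker concentrations
with clinical covariates and radiologist-annotated CT features of the
nodule to produce a continuous malignancy confidence score.

Because no patient-level data are publicly available, the package also
contains a synthetic cohort generator calibrated to the published
class-conditional summary tables, so the entire pipeline is exercisable and
testable end to end.

## Synthetic cohort generator

**Concentrations.**  Each marker, in each class (malignant / benign), is
modelled as a log-normal whose arithmetic mean and SD equal the published
values via the closed-form moment match
`scale^2 = ln(1 + sd^2/mean^2)`, `location = ln(mean) - scale^2/2`.
A log-normal is the natural choice: concentrations are nonnegative, and in
every published entry the SD exceeds the mean (strong right skew), which a
normal law cannot represent without negative mass.  Two printed moments
exactly determine the two parameters.

**Independence.**  Markers are sampled independently within a patient; no
between-marker correlation is published.  A Gaussian-copula hook
(`CohortConfig.marker_correlation`) accepts a 7x7 correlation matrix for
sensitivity analyses but defaults to independence.  A practical consequence
(verified in the test suite): under independence the *combined* panel
positivity in the simulated malignant class is about 70%, higher than the
published 60.7%, because real markers are positively correlated (patients
positive for one marker tend to be positive for others, so the disjunction
gains less).  The generator therefore calibrates to the published
*per-marker* rates; combined rates are emergent, and published combined
rates are checked by desk arithmetic on the printed counts instead.

**Categorical features.**  Gender, age band (<=60 / >60), smoking history,
nodule count, CT composition (GGO / pGGN / mGGN / solid), the five binary
imaging signs (vessel, spiculation, lobulated, pleural indentation,
bubble-like) and tumour stage are drawn class-conditionally from the
published frequency tables, independently given the class (only marginals
are published).  Stage is assigned to malignant records only.

**Diameter.**  Lesion diameter is drawn per class from a log-normal matched
to the published mean/SD (16.5/9.0 malignant, 12.4/5.7 benign).  The source
table labels the column "cm", which is inconsistent with its own 8/20/30 mm
size bins and with nodule biology (a 16.5 cm mean nodule is implausible);
the values are treated as mm.  Size-bin membership (<=8, 8-20, 20-30,
>30 mm) is **derived** from the sampled diameter, never sampled separately,
so bins and diameters can never contradict each other — the price is that
derived bin frequencies follow the fitted log-normal rather than the
published bin table (e.g. ~12% of simulated malignant nodules fall in the
<=8 mm bin vs. 18.1% published; the two published summaries are not
mutually consistent with any single two-parameter law).

**Cohort presets.**  `full_cohort_config()` (571 malignant / 362 benign)
uses the full-cohort marker moments and demographics;
`nodule_cohort_config()` (459 / 285) uses the nodule-subcohort moments and
is the default input for the network.  Imaging/nodule features are only
published for the nodule subcohort; the full-cohort preset reuses those
tables so every record carries the complete feature schema.

**Default cutoffs.**  The assay kit's cutoffs are not published.  The
default cutoff for each marker is the `1 - rate_malignant` quantile of the
malignant-class log-normal, so simulated malignant patients are positive at
exactly the published per-marker rate by construction.  The benign rates
then emerge from the benign law; for P53 the emergent benign positivity is
~4.3% against 5.0% published, and all markers land within 3 percentage
points.  Cutoffs are always overridable.

**What the generator does not emulate:** ELISA plate/batch effects, assay
drift, marker correlation (by default), feature dependence beyond the class
label (e.g. composition and diameter are conditionally independent given
malignancy, which is not true of real nodules), and longitudinal growth.
Passing tests therefore demonstrate correctness of the pipeline under the
published marginal structure, not real-data performance.

## Panel statistics

* **Positivity** is strict (`concentration > cutoff`); a value exactly at
  the threshold is negative.
* **Clopper-Pearson intervals** use the Beta-quantile form,
  `low = B(alpha/2; k, n-k+1)`, `high = B(1-alpha/2; k+1, n-k)`, with the
  conventional endpoints 0 at k=0 and 1 at k=n.  The test suite checks them
  against an independent binomial-tail-inversion root finder to 1e-6.
* **Mann-Whitney U** uses midranks for ties.  When both groups have at most
  8 observations the two-sided p comes from full enumeration of all
  `C(n1+n2, n1)` rank assignments (exact even under ties); otherwise a
  normal approximation with tie correction and **no** continuity
  correction.  Degenerate data (all values identical) give p = 1.
* **Chi-square (2x2)** is the Pearson statistic without continuity
  correction by default (all published tables have large counts); the Yates
  correction is available by flag.  Zero margins are an error.
* **ROC/AUC** groups tied scores at a single threshold and integrates by
  the trapezoid rule, which makes the AUC equal to the pairwise
  concordance probability with ties counted 1/2 (checked against an O(n^2)
  oracle).
* **Panel ROC.**  A single binary call has no threshold to sweep, so the
  published AUC of the combined binary test (0.7448) is not reconstructible
  from a binary output.  The package exposes two documented continuous
  surrogates: per-marker concentration ROCs, and the marker-count score
  (number of positive markers, 0-7), which is what the evaluation harness
  uses for the panel arm.  No claim is made of matching 0.7448.

## Feature encoding

The 7 concentrations are z-normalized per marker, `x -> (x - mu)/sigma`,
and concatenated into one 7-dimensional continuous feature; diameter is
z-normalized the same way as its own 1-dimensional feature.  `mu` and
`sigma` (population SD, divide by n — the convention is immaterial at
cohort sizes but fixed for reproducibility) are computed **on the training
split only** and persisted with the model: normalizing over all patients
including the evaluation split would leak test statistics into training.
Each discrete feature becomes a one-hot vector over its fixed category
list; an unseen category at transform time is an error, and missing values
are never imputed.

## Network

Each input feature i (dimension `dim_i`) has its own dense encoder
`Encoder_i : dim_i -> 32`; the encoded vectors are averaged element-wise
(mean pooling) into `h` (32); two further dense layers map
`h -> 32 -> 1`.  Every dense layer computes `tanh(x W + b)`, including the
output, so the confidence score y lies in (-1, 1).  Mean pooling makes the
score invariant to permuting features together with their encoders.

Training choices were genuinely open (no objective, optimizer, split or
regularization is published) and are fixed as: squared-error loss against
labels coded -1/+1 (matching the tanh head; a sigmoid/cross-entropy head is
selectable), plain mini-batch gradient descent with learning rate 0.01,
batch size 32, 200 epochs, parameters kept at the best validation loss;
initialization uniform(-s, s) with `s = 1/sqrt(in_dim)`; stratified
70/15/15 train/validation/test split.  All randomness (init, shuffling,
splits) derives from one seed, so a fixed seed gives a bit-identical
trajectory.  Gradients are hand-written reverse mode and validated against
central finite differences (relative error < 1e-5) across layer shapes.

On the default calibrated nodule cohort the network reaches held-out AUC
around 0.98 and clearly exceeds the panel's marker-count AUC (~0.7-0.8),
a qualitative echo of the published improvement of the combined model over
the panel alone — qualitative only, since the synthetic cohort's
conditional-independence structure makes the classes more separable than
real patients plausibly are.  A label-permutation null run lands at AUC
0.5 as it must.

## Evaluation harness

All methods are scored on the identical held-out rows (the report records a
hash of the fold assignment).  The panel arm uses the combined call for
sensitivity/specificity/accuracy and the marker-count score for ROC.
Recall equals sensitivity by definition; F1 = 2PR/(P+R) with malignant the
positive class.  Stratified k-fold cross-validation reports per-metric mean
and SD and refuses folds that lack a class.

## Problem sizes and numerical choices

Calibration checks use 50,000 patients per class (marker-mean tolerance:
3 standard errors; category frequencies: +-1 percentage point).  Monte-Carlo
oracles use 10^6 draws.  The network tests train on the preset-size cohort
(744 patients) and, for the permutation null, on a 3,000-patient cohort to
keep the null AUC's sampling noise well inside the +-0.05 band.  Exact
Mann-Whitney enumeration is limited to 8 per group (12,870 assignments at
worst).  Tolerances: moment round-trips 1e-9, gradient checks 1e-5
relative with step 1e-5, ROC-vs-concordance 1e-12.

## Known limitations

* Synthetic cohorts inherit every simplification listed above; absolute
  metric values on them (e.g. the 0.98 AUC) say nothing quantitative about
  real patients.
* The published combined-test AUC and the published subgroup confidence
  intervals are internally inconsistent with the printed counts and are not
  reproduced (see the panel ROC note; e.g. a printed 95% CI of
  49.9-68.3% around 60.7% at n=571 is far wider than any exact binomial
  interval at that n).
* Source tables disagree in places (benign combined positives 67 vs 71;
  a narrative CAGE mean of 11.80 vs 3.44 in its table; the "cm" diameter
  header).  The generator calibrates to the tabulated per-marker values and
  treats diameters as mm.
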