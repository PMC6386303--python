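# Methods

This note documents the statistical model behind `euslymph`, the
parameters that matter, what the simulator does and does not emulate, and
the numerical conventions the implementation fixes.

## Setting

A cohort of lymph nodes is observed by EUS; each node has a long and short
axis (mm, measured by a non-rating individual), a location, and a
ground-truth diagnosis (malignant / benign, from EUS-guided fine-needle
aspiration or resection). A panel of R raters (default 5) assigns each
node a category for six image features: shape (round / oval / triangle /
polygonal), border (clear / fuzzy), margin (regular / irregular),
echogenicity (dark / intermediate), homogeneity (homogeneous /
heterogeneous), and hilum (present / absent). The workflow screens
features by inter-rater agreement, consolidates ratings by majority vote,
derives size cutoffs by ROC, scores two unweighted count-based criteria
sets, and compares them head to head.

## Agreement model

**Statistic.** Fleiss' fixed-marginal multi-rater kappa, computed per
feature from the complete-case per-lesion count matrix. A (lesion,
feature) cell missing any rater is excluded from kappa and from consensus
for that feature (complete case, logged with counts); no imputation is
attempted. When all ratings fall in one category, chance agreement is 1
and kappa is undefined — the implementation raises an explicit error
rather than returning 0, 1 or NaN.

**Confidence intervals.** Percentile bootstrap over lesions (B = 2000 by
default, raters kept intact, seeded). Bootstrap resamples with undefined
kappa are redrawn up to a retry cap and then dropped with a warning. The
percentile interval need not contain the point estimate exactly; the
package asserts containment only with 0.01 resampling slack. A bootstrap
was chosen for its distribution-free behavior at n = 68; no attempt is
made to reproduce any particular closed-form interval.

**Interpretation bands** (Landis–Koch): < 0 less than chance; (0, 0.20]
slight; (0.20, 0.40] fair; (0.40, 0.60] moderate; (0.60, 0.80]
substantial; > 0.80 almost perfect. Feature selection admits features
with kappa strictly above 0.4 (configurable).

**Consensus.** The category with >= 3 of 5 votes wins; with four shape
categories no category may reach 3 votes, in which case the 4-way
consensus is recorded as indeterminate. The criteria never consume the
4-way consensus, only the round-or-oval distinction, so shape is first
binarized per rater (round-or-oval vs other) and then majority-voted —
with an odd panel this always yields a decision. This binarize-then-vote
rule is this package's convention for cells without a 3-vote category.

## Criteria and evaluation

**Cutoffs.** Youden's J is maximized over midpoints between consecutive
distinct observed values, with "positive" meaning strictly above the
threshold; ties in J break toward the higher cutoff (higher specificity).
The result is rounded to a clinical grid (default 5 mm, half rounds up),
which maps the development cohort's 19.7 / 10.7 mm to 20 / 10 mm. A 1 mm
grid would give 11 mm for the short axis; the 5 mm default is what
reproduces the clinically used 20/10 pair.

**Scores.** New = {long > 20 mm} + {short > 10 mm} + {consensus
round-or-oval and ratio > 0.5}; old = {long > 10 mm} + {consensus round} +
{consensus clear border} + {consensus dark echogenicity}. "Sharp border"
and "hypoechoic" in the historical criteria map to the categories "clear"
and "dark". All inequalities are strict by default and configurable. The
long-short ratio is short/long in (0, 1] (1 = perfectly round), so
"> 0.5" selects rounder nodes; the ratio is computed from the measured
axes and is rater-independent.

**Group comparisons.** Continuous variables: Wilcoxon rank-sum (exact
enumeration for tie-free samples with both n <= 10, otherwise the normal
approximation with mid-ranks, tie correction and continuity correction).
2x2 indicator tables: Fisher's exact test (two-sided, sum of tables no
more probable than observed) whenever any expected count is below 5, else
Pearson chi-square without continuity correction; a zero margin returns
p = 1 flagged degenerate.

**ROC and AUC.** One operating point per distinct score threshold
(positive = score >= t) plus the trivial endpoints. AUC is computed both
as the trapezoidal area and as the tie-corrected Mann–Whitney placement
mean, and the two are asserted equal to 1e-12 on every call. Paired
comparison is DeLong's test on placement-value covariances with unbiased
(ddof = 1) covariance estimates; a zero-variance difference is flagged
degenerate with p = 1. The AUC interval is Wald from the DeLong variance;
binomial metrics carry Wilson score intervals (several published-style
interval conventions are mutually inconsistent at these sample sizes, so
no specific printed interval is targeted).

**Accuracy-table audit.** `ppv_npv_from_sens_spec` reconstructs integer
confusion counts from a printed sensitivity/specificity pair and the class
sizes (round half-up), then recomputes accuracy/PPV/NPV. With the 30/38
composition this reproduces every printed accuracy/PPV/NPV cell of the
development study's table to one decimal, which is the audit that this
package's metric definitions match the published ones.

## Synthetic cohort

Defaults emulate the development cohort: n = 68, prevalence 30/68,
class-conditional parameters from its published comparison table.

* **Long axis** ~ lognormal, moment-matched to the published mean ± SD
  (malignant 25.3 ± 11.3 mm, benign 16.8 ± 8.1 mm). Node sizes are
  right-skewed and positive; a lognormal with these moments also
  reproduces the published exceedance rates (e.g. malignant
  P(long > 20) = 0.632 vs printed 63.3%, benign 0.271 vs 23.7%) that a
  symmetric truncated normal overstates badly on the benign side.
* **Long-short ratio** ~ normal truncated to (0.05, 1], with parent
  parameters solved numerically so the realized truncated moments equal
  the configured mean ± SD (malignant 0.66 ± 0.21, benign 0.59 ± 0.17).
  Short axis = long x ratio, so axis ordering holds by construction.
* **Shape** ~ class-conditional categorical with the published count
  fractions (malignant 8/14/0/8 of 30; benign 4/18/5/11 of 38).
* **Binary descriptors**: Bernoulli on the malignant-looking category
  (clear border, irregular margin, dark, heterogeneous, absent hilum).
  The published table prints no class marginals for these, so they are
  free parameters: the generic default is 0.7 (malignant) / 0.3 (benign);
  the *study-conditions* configuration (`study_cohort_config`) sets them
  class-equal at 0.5, because the historical criteria — half of whose
  items are these descriptors — performed at chance level (AUC 0.52) in
  the development cohort.
* **Rater noise**: each rater reports the true category with probability
  1 − ε, else a uniformly random different category (symmetric uniform
  confusion; no rater-specific skill, no inter-feature correlation). For
  a binary feature this model has the closed form
  κ∞ = 1 − ε(1 − ε)/(p(1 − p)) with p the marginal category rate; for the
  4-way shape, agreement is (1 − ε)² + ε²/3 against pooled marginals
  q_j(1 − ε) + (1 − q_j)ε/3. Inverting these at the published kappas
  gives the calibrated defaults ε = {shape 0.235, border 0.2655,
  margin 0.5, echogenicity 0.2125, homogeneity 0.208, hilum 0.2655},
  which reproduce the published panel's kappas (0.44, 0.22, ~0, 0.33,
  0.34, 0.22) within ~0.01 at large n. The published margin kappa of
  −0.02 cannot arise in expectation from symmetric noise (its infimum is
  ~0 at ε = 0.5), so margin uses chance-level ε = 0.5.

**What the simulator does not emulate.** Items are drawn independently
within a lesion: real cohorts couple size, shape and ratio, which is why
the full generator pipeline separates the classes less sharply (new-score
AUC ≈ 0.72 at the study conditions) than the real cohort (0.82). The
direction-of-effect experiment therefore has two designs: the
*marginal-anchored* design draws per-lesion criteria-item indicators
directly from the published class-conditional rates and reproduces the
published AUC levels (mean ≈ 0.82 new vs ≈ 0.56 old; new > old in
>= 95 of 100 replicates at n = 68), while the end-to-end generator design
is held to the weaker mean-direction assertion it can support. Passing
tests on synthetic data show the machinery is correct under the stated
model, not that the criteria generalize to new patient cohorts.

## Numerical conventions and degenerate inputs

Axis ordering is repaired (swap + warning) at read time, since tables are
human-entered; the in-memory record rejects violations. Categories are
case-insensitive on input and canonical lower-case internally. Youden
derivation requires both classes and at least two distinct values; ROC
and metrics report undefined quantities (empty denominators) as explicit
`None`s with flags rather than NaN. All randomness flows through named
integer seeds (cohort, panel, bootstrap seeds are spawned from one master
seed per run); reports are byte-deterministic given the seed and embed a
run record (package version, seeds, full config).

## Problem sizes used in checks

Large-sample calibration checks use 4,000–10,000 lesions (moment
recovery, kappa calibration, population Youden cutoff within 2 mm of a
fine-grid oracle); bootstrap-coverage uses 100 replications of n = 500
with B = 1,000; direction-of-effect uses 100 replicates at the cohort's
own n = 68. These sizes make Monte-Carlo error small relative to each
stated tolerance while keeping the default suite fast.

## Known limitations

* Rater noise is exchangeable across raters; per-rater bias/skill and
  ordinal weighting of categories are out of scope.
* Bootstrap CI method and the Wilson metric intervals are package
  conventions; published interval columns are not reproduction targets.
* No cross-validation or external validation of derived cutoffs is
  modelled; cutoffs are derived and evaluated on the same cohort, as in
  the development study design.
* The 4-way shape consensus can be indeterminate; downstream criteria are
  unaffected (they consume the binarized decision), but the 4-way
  consensus table reports such cells explicitly.
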