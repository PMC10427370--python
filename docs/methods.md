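# Methods

This note documents the statistical procedures implemented in
`hmcresponse`, the design choices made where several reasonable options
existed, what the synthetic-cohort generator does and does not emulate,
and the package's known limitations.

## Normalization and differential testing

Size factors are classical median-of-ratios: for genes with nonzero
counts in every sample, `s_j = median_g (c_gj / geomean_g)`. The median
is taken on the ratio scale (not in log space); with an even number of
reference genes the two differ slightly, and the ratio-scale form is
what the brute-force oracle in the test suite checks against. TPM uses
per-gene lengths in kilobases and rescales each column to 10⁶. The
`rlog_approx` transform is `log2(c/s + 1)`; unlike the full
regularized-log it applies no shrinkage of low-count genes toward the
trend, which is inconsequential at the depths the pipeline targets
(≥10⁶ reads/sample) but will overstate the variance of near-zero genes
in shallow libraries.

The two-group negative-binomial test works on size-factor-normalized
counts. Per gene, the dispersion is estimated by the method of moments
from the pooled within-group variance (`Var(y/s) ≈ μ·mean(1/s) + d·μ²`),
floored at 10⁻⁸, and shrunk 50/50 in log space toward an ordinary
least-squares trend of log dispersion on log mean. The log fold change
is the log ratio of group means (half-a-count continuity on the group
mean scale keeps it finite); its standard error comes from the delta
method, `Var(log m̂) = (1/n²)(Σ_j 1/(m s_j) + n·d)`. The Wald statistic
is referred to a t distribution with `n_A + n_B − 2` degrees of freedom
rather than the normal: with the 2-vs-2 and 10-vs-10 designs this
pipeline uses, the normal reference is anti-conservative, and the t
reference brings the null rejection rate at p < 0.05 to ~0.044 in the
5000-gene calibration the acceptance suite runs. Genes with zero counts
in every sample are dropped before testing with a logged count.

Threshold conventions are deliberately asymmetric between the two gene
classes: DEGs use the adjusted p (`p_adj ≤ 0.1`, inclusive) while DhMGs
use the raw p with a strict inequality (`p < 0.01`), both with
`|log2FC| ≥ 0.5` inclusive. Independent filtering on mean expression is
off by default and available as a flag. Per-patient DhMG tests pool the
two tissues as replicates (BM + PB at each day, a 2-vs-2 design);
whether to test tissues separately is exposed via the `tissues`
argument.

## Digital cytometry

The signature is built by, for each of the 13 cell types, ranking genes
by the fold of that type's reference expression over the **maximum** of
the other twelve and keeping the top `markers_per_type` (default 50)
with fold > 1. This is simpler than a condition-number sweep but
transparent and reproducible; the condition number of the resulting
matrix is reported. Fraction estimation solves one non-negative least
squares problem per sample in linear TPM space (no log transform — the
mixing model is linear in abundance), then rescales the weights to
proportions, which makes the estimate invariant to the overall scale of
each bulk column. NNLS replaces the ν-SVR engine of CIBERSORT-style
tools: it is deterministic, dependency-light and adequate at this
problem scale. No batch correction is implemented; a per-batch median
scaling can be applied upstream if needed. Malignant (6 types) and
immune (7 types) compartments are renormalized to sum to 1 separately;
tissue averaging takes the arithmetic mean of BM and PB fractions per
patient, which stays on the simplex, so no renormalization is
reapplied.

## Enrichment

Preranked GSEA uses the weighted KS running sum: hits increment by
`|stat|^α / Σ_hits |stat|^α` (α = `weight_exponent`, default 1; α = 0
gives the hand-checkable unweighted walk), misses decrement by
`1/(N − N_hits)`, ES is the signed maximum deviation. The null is
gene-label permutation (random same-size sets), the standard choice for
preranked inputs; NES divides ES by the mean |null ES| of matching
sign, and the two-sided p is the sign-matched tail frequency with
resolution `1/(n_perm + 1)`. Rankings break ties by gene id after the
statistic, so results are deterministic.

The per-sample score is `(mean rank of set genes − mean rank of
non-set genes)/N` with ranks computed within each sample. It is a
deliberately simple single-sample statistic: invariant to any monotone
transform of a sample's expression, cheap, and adequate for comparing
the same set across samples. It is *not* numerically equal to GSVA's
KS-based score; analyses that depend on GSVA's exact values should use
GSVA. Weighted signature scores (e.g. LSC17) are
`Σ_g w_g log2(TPM + 1)`; the 17 LSC17 coefficients are not shipped and
must be supplied as a gene→weight table.

## Co-expression modules

Pearson correlations between DEG pairs are computed on
variance-stabilized log expression; zero-variance genes are dropped
with a warning. Modules come from agglomerative clustering of the
**rows of the correlation matrix** under Euclidean distance (the
alternative — clustering expression rows directly — is a flag), with
average linkage (unstated in the original description; average linkage
is the robust default for correlation profiles and is recorded in the
output metadata) and the tree cut at k = 4 by default. Network
extension adds first-order neighbors from a user-supplied edge list
when their mean expression exceeds 3 TPM (strict inequality), tagging
added genes with provenance; it is monotone in the edge list.

## Classifiers

Composition scores are linear combinations of patient-level fractions;
`nk_plus_gmp` is the plain sum of the two fractions (a fitted logistic
combination is available but not the default, as the sum needs no
training data). ROC/AUC is the Mann–Whitney statistic with ties
counted 0.5.

The 5hmC signature classifier is a gradient-boosted tree ensemble
(depth 3, 100 rounds, learning rate 0.1, binary logistic objective)
on `rlog`-transformed per-gene 5hmC levels, with both Day 0 and Day 5
samples as training points and responders (CR + CRi) as the positive
class. Cross-validation is patient-based: folds partition patients
into k groups balanced to ±1 patient, and an assertion fails any fit
in which a patient contributes to both a training and validation set.
Two deviations from plain defaults matter:

* **Column subsampling** (`colsample_bytree = 0.1`, engaged only above
  200 features). With thousands of correlated features and a few dozen
  patients, deterministic full-column trees put every split on one
  member of each correlated block, so split-count importance covers
  only ~30 genes and is unstable across seeds. Subsampling spreads
  split credit across blocks; in the planted-gene benchmark it raises
  top-30 recovery of 30 informative genes from ~0.5–0.8 (seed
  dependent) to a stable 0.87–0.97. Narrow refits (e.g. a selected
  top-11 signature) use all columns.
* **CV metric**: the default CV AUC is the mean of per-fold
  out-of-fold AUCs, not the AUC of pooled out-of-fold probabilities.
  Pooled probabilities carry fold-specific calibration offsets that
  anti-correlate with the validation fold's class balance in small
  cohorts, biasing the pooled AUC below chance under the null
  (measured ≈0.38 at 22 patients, vs ≈0.47–0.51 for fold averaging).
  Pooling remains available via `cv_metric="pooled"`.

Importance is the split count ("F score") from a final fit on all
training samples; `select_top_k_refit` sweeps a k grid, refits on the
top-k genes per k, and keeps the smallest k maximizing the CV AUC.
The shuffled-label control permutes responder status across patients
(keeping all samples of a patient consistent) and repeats the CV;
its mean over 20 shuffles sits at chance level. Fold assignment is
random by patient, not stratified by response; a stratified option
exists.

## Survival analysis

The Kaplan–Meier estimator is the standard product limit; censored
times reduce the risk set without a step. The log-rank test sums
observed-minus-expected events over event times with the
hypergeometric variance and refers the squared ratio to χ²(1). The
Cox model maximizes the Breslow partial likelihood by Newton–Raphson
(gradient tolerance 10⁻⁸, 50 iterations max); Breslow ties were chosen
for hand-checkability — with the three-record example the score
equation solves in closed form to β = −ln(2)/2. Monotone likelihood
(perfect separation) is detected when the fitted log-hazard spread
exceeds 15 (hazard ratios beyond e¹⁵ have no finite MLE worth
reporting) and raised as an error rather than returned as a huge
coefficient with a flat information matrix. Covariates are centered
before fitting (pure numerics; the estimate is unchanged).
Multivariable models include age (continuous) and sex (indicator).

The median split assigns values strictly above the median to "high"
and everything else — including exact ties — to "low"; this tie rule is
arbitrary but fixed and documented. The Day 0–Day 5 Spearman statistic
uses BM only by default (matching the paired-BM design of that
analysis); DhMG counts pool BM + PB.

## The synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, plus complete ground truth:

* **Reference profiles**: 13 columns, log-normal baselines (mean ≈5),
  disjoint blocks of 50 markers per type elevated 10-fold, mild
  type-specific noise so off-marker columns are not collinear.
* **Bulk RNA**: per-sample fractions from a Dirichlet whose
  concentrations give GMP-like and HSC-like mean fractions ≈0.2 (the
  original cohort's true fractions are unknown; these are generator
  parameters, not biological claims); responder labels are Bernoulli
  with log-odds `response_effect × ((f_GMP − f_HSC) + f_NK)`; counts
  are negative binomial (dispersion 0.05) around
  `depth × mixture × gene length`, so TPM correctly recovers the
  mixture. Gene lengths are log-uniform on 0.5–10 kb.
* **5hmC cohort**: per-patient baselines share a log-normal patient
  effect (sd 0.4) across tissues with small tissue noise (sd 0.1),
  which produces the BM/PB concordance the pipeline checks; Day 5
  means shift a dose-dependent random gene fraction
  (1% / 3% / 8% of genes at 37.5 / 50 / 75 mg/m²) by ±1.5 log2 units;
  30 response-informative genes differ between responders and
  non-responders by 1.5 log2 units. An optional `architecture_seed`
  pins the gene architecture so independently generated cohorts (train
  and held-out test) share it.
* **Survival**: exponential with log-hazard
  `log(1/365) − 0.01 × |shifted gene set|` (days), so stronger
  epigenetic responsiveness means longer survival; censoring replaces
  the event with a uniform draw on (0, t) at rate 0.3.

Default problem sizes used in tests and the acceptance script — 2000
genes, 22–60 patients, 20 shuffles/replicates — are desk-scale choices
that keep full runs fast while leaving all planted effects well
resolved; the structure, not the scale, is what the tests certify.

What the generator does **not** emulate: batch effects beyond a scale
factor, AML genotypes and cytogenetics, realistic gene–gene correlation
beyond the planted blocks, library-preparation artifacts, and any
coupling between the RNA and 5hmC modalities other than shared label
structure. Passing tests therefore demonstrate that the implementations
recover what they are designed to recover under the stated model — not
that the biological conclusions transfer to any particular real cohort.

## Numerical conventions and degenerate inputs

Ranking ties break by gene id; fold assignment and all stochastic
steps take explicit seeds; `fcluster` module ids are relabelled by
first appearance so clustering is order-stable. All-zero genes are
dropped (differential testing), zero-variance genes are dropped
(correlation), constant responsiveness values refuse a median split,
a compartment with zero estimated mass yields NaN fractions with a
warning, single-class training folds predict a constant probability,
and a patient appearing in both train and test sets is a hard error
everywhere.

## Limitations

The NB test fits no covariates (no tissue term, no paired-sample
term); dispersion shrinkage is a fixed 50/50 blend, not an empirical
Bayes posterior; the per-sample enrichment score approximates, but
does not reproduce, GSVA; NNLS deconvolution has no batch correction
and no absolute mode; the Cox implementation handles neither
time-varying covariates nor competing risks; and boosting
hyperparameters are sensible defaults rather than tuned values — the
original analysis's exact settings are not recoverable from its
description.
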