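# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic studies, the defaults and why they
were chosen, and the numerical/design decisions a maintainer should know.

## 1. Biomarker discovery from extreme cell lines

Drug activity per cell line is taken on a **higher = more sensitive** scale
(a −log GI50-like convention; percent-kill data fits directly). The top
⌈f·n⌉ and bottom ⌈f·n⌉ lines by activity are labeled sensitive/resistant;
the tail fraction f defaults to 0.30 per tail, configurable per tail as a
pair (asymmetric designs are common when the activity distribution is
skewed). The recommended operating range for f is 0.10–0.35; values outside
it are accepted with a warning because asymmetric panels can require a
slightly larger tail. Ties at a tail boundary pull every tied line in, so
only activity *ranks* matter — the labeling is invariant to monotone
transforms of the activity scale.

Genes are scored by a **Welch two-sample t** between the extreme classes.
A two-group comparison was chosen over correlation with the continuous
activity because the extremes are what define the phenotype of interest and
the t gives an immediately usable p-value; on the extremes its ranking is
equivalent to a point-biserial correlation. The initial screen keeps genes
with p < α (default 0.05) truncated to the top `max_genes` (default 500) by
|t|; no multiple-testing correction is applied at this stage since the
screen only feeds later, stricter filters.

Two filters follow. The **FFPE-robustness filter** restricts to a supplied
set of genes whose measurements survive formalin fixation (in a real study
this list comes from paired frozen/FFPE profiling; in the synthetic study it
is generated, see §5). The **direction-consistency filter** recomputes the
sign of (mean responder − mean non-responder) in an independent treated
patient cohort and keeps a gene only when it matches the cell-line
direction; a zero patient difference counts as inconsistent. Under a null
cohort this filter keeps ~50% of genes (sign agreement is a coin flip),
which the tests verify.

## 2. Concordance ("correlation of correlations")

For candidate genes measured in both the cell panel (A) and a patient
cohort (B), each set's gene–gene Pearson correlation matrix is computed on
the identical gene list. A gene's concordance coefficient is the Pearson
correlation of its two correlation vectors with the self-entry removed —
+1 when the gene has the same co-expression neighbourhood in both sets, −1
when the neighbourhood is inverted.

Significance is assessed by **permuting gene identities of B's correlation
matrix** (rows and columns together) and recomputing the coefficients:
p = (1 + #{|null| ≥ |obs|}) / (B + 1), two-sided. Permuting *samples* of B
would destroy B's correlation matrix itself rather than break the A↔B gene
matching, so gene-identity permutation is the null that tests exactly the
concordance claim. Defaults: α = 0.05, B = 1000. When several measurements
map to one gene symbol across platforms, the one with the highest mean
expression in its own cohort is kept (the dominant convention).

Selected genes are ordered by the discovery |t|, and provenance (filter
name, counts before/after) is carried on the biomarker set; counts are
non-increasing along the chain by construction.

## 3. Diagonal LDA with nested leave-one-out cross-validation

With 18–60 cell lines and tens-to-hundreds of genes the pooled covariance
is singular, so the discriminant assumes a diagonal covariance:

d(x) = Σ_g (μ_{s,g} − μ_{r,g}) (x_g − (μ_{s,g}+μ_{r,g})/2) / σ²_g + log(π_s/π_r)

with pooled per-gene variance σ²_g and empirical class priors π. Genes with
zero pooled variance are dropped with a warning.

Feature count and performance are handled by **nested LOOCV**: the outer
loop holds out one line at a time; within each outer training fold an inner
LOOCV re-ranks genes by |Welch t| and picks the candidate feature count k
with the best inner accuracy (smallest k on ties). The outer estimate is
therefore free of selection leakage — the test suite demonstrates that a
deliberately leaky variant (genes ranked once on all samples) is measurably
optimistic on null data, while the nested estimate averages 0.50. The final
model is refit on all lines with the k selected by inner CV on the full
panel. Candidate feature counts default to {5, 10, 20, 50, 100}.

Note that in the full pipeline the *discovery screen itself* sees the same
panel, so the reported `cv_accuracy` is a training-panel CV accuracy, not an
unbiased generalization estimate, whenever α < 1 or `max_genes` truncates.
The calibration experiments (§6) therefore run with the screen disabled.

Cohort scoring drops model genes missing from the target matrix (refusing
transfer when fewer than half remain) and standardizes raw discriminants
within the cohort (z-scores, ddof = 1); cohort-level standardization is what
makes scores comparable across platforms and cohorts. A degenerate cohort
(all scores equal) gets z = 0 with a warning. The combination score is
(z₁ + z₂)/√2 — unit variance if the drugs act independently — then
re-standardized; it is symmetric in its arguments. Raw discriminants and
posterior probabilities were considered and rejected for combination: they
are not comparable across predictors trained on different panels.

## 4. Clinical evaluation

A patient is *predicted responder* iff score ≥ threshold (ties predict
responder); clinically, responder = complete response, non-responder = PR /
SD / PD. Components:

* **Wilcoxon rank-sum**, exact enumeration when both groups have ≤ 8
  observations and no ties, otherwise the tie-corrected normal
  approximation.
* **AUC** computed as Mann–Whitney U / (n₁n₀) with ties counted ½; 95% CI by
  percentile bootstrap over patients (default 2000 resamples, seeded;
  resamples that lose a class carry no AUC and are discarded).
* **Cutoffs** over the candidate grid of midpoints between consecutive
  sorted unique scores plus ±∞: the **Youden rule** maximizes
  J = sensitivity + specificity − 1; the **NPV-max rule** maximizes NPV
  subject to at least `min_predicted_negatives` (default 3) predicted
  non-responders, because an unconstrained maximizer returns a vacuous
  NPV = 1 on a one-patient tail. Ties break toward higher sensitivity, then
  lower threshold. The NPV rule exists because a balanced cutoff still
  mislabels ~15% of true responders — clinically unacceptable when the
  downside is withholding effective therapy; maximizing NPV instead makes
  "predicted non-responder" a reliable label. When all scores are equal the
  only admissible threshold is the degenerate all-negative rule (+∞), which
  is returned as such.
* **Confusion metrics** with 95% Wald intervals p̂ ± 1.96·√(p̂(1−p̂)/n)
  truncated to [0, 1], and the odds ratio with the Woolf log interval
  exp(ln OR ± 1.96·√(Σ 1/cell)); the Haldane 0.5 correction is applied to
  all four cells iff any cell is zero and flagged on the result. Wald and
  Woolf were chosen because recomputation shows they reproduce the published
  validation tables exactly (e.g. 4/7 → 0.571, CI 0.205–0.938; OR 7.16, CI
  1.315–38.91) — validated, not assumed. Undefined margins (empty predicted
  class) yield NaN metrics, not exceptions.
* **Survival**: overall survival beyond a horizon (default 60 months) is
  administratively censored — late deaths say little about chemotherapy
  response and a few long survivors otherwise dominate the tail. Groups are
  compared with Kaplan–Meier curves and the unweighted (Mantel–Haenszel)
  log-rank test via lifelines; the group median is the earliest time with
  S(t) ≤ 0.5 (NaN when never reached).
* **Adjusted logistic regression** of response on score plus covariates
  (categoricals reference-coded) via statsmodels' Newton/IRLS fit,
  tolerance 1e-8, max 100 iterations; non-convergence and perfect
  separation raise.

## 5. The synthetic study generator

`simulate_cell_panel` draws standard-normal activity per line and builds
expression as baseline + planted effect + latent factors + noise:
informative genes add direction · effect_size · standardized activity;
concordant genes each load (±`latent_loading`, default 1.0) on one of
`n_factors` (default 4) shared latent factors; everything else is
N(baseline, noise_sd²). Informative genes are drawn into the concordant set
first — drug-associated genes are assumed co-regulated in vitro and in
vivo, which is precisely the premise that makes cell-to-patient
extrapolation possible; a generator violating it would be simulating a
world where the method cannot work.

`simulate_patient_cohort` reuses the panel's factor loadings with fresh
patient-level factor scores (this shared low-rank structure is what plants
a concordance signal); non-concordant genes get independent factor
structure of the same density. Responders (Bernoulli, default rate 0.58,
matching a 32-of-55 complete-response cohort) differ from non-responders by
effect_size · noise_sd on informative∩concordant genes in the planted
directions. Survival is exponential — responder median 60 months, hazard
ratio for non-responders default 2.5 — under independent censoring
(uniform on [0, 240] months, administrative at 120). Cohort sizes default
to 55; the calibration experiments use 100.

`simulate_ffpe_pair` keeps an exact-count random fraction (default 0.55) of
genes "FFPE-robust": robust genes get the frozen values plus small noise
(0.3 · noise_sd), non-robust genes are redrawn around their own mean/SD —
total signal loss, near-zero frozen-vs-FFPE correlation. A precomputed
robust set can be passed in so one study degrades every cohort with the
same set, as robustness is a property of a gene. Robustness is *planted*,
not inferred — the criterion used on real paired frozen/FFPE data to call a
probe robust is a property of the assay, not of this method.

Every operation draws from its own stream seeded by (seed, operation-id):
identical configs are bit-reproducible and the three operations never share
randomness.

What the generator does **not** emulate: probe-level intensity
distributions, batch/platform effects, non-exponential survival,
confounding between response and covariates, and correlated drug responses
(drugs get disjoint informative gene sets). Passing tests therefore show
the machinery is correct and calibrated under the model's own assumptions,
not that real cohorts will reach these effect sizes.

## 6. Pipeline and calibration experiments

The two-drug pipeline simulates a panel per drug (drugs are trained on
different panels, as when one drug's data comes from a different screen), a
shared training cohort (direction + concordance filters), a frozen test
cohort (cutoff derivation + evaluation) and an FFPE validation cohort
scored with the *locked* cutoffs — the prospective-validation design.
Per-stage seeds derive deterministically from one master seed; the JSON
report embeds the full config, so a report suffices to re-run identically.

`coxen.experiments` packages the two standard validations. **Null
calibration** (effect 0, hazard ratio 1, filters at α = 1 so a global null
cannot empty the gene list, |t| screen untruncated so the CV estimate is
leakage-free): across 200 runs the nested-CV accuracy and combination AUC
average 0.50 and the Wilcoxon/log-rank p-values are uniform. **Signal
recovery** (defaults: effect 1.5, 60 lines, cohorts of 100): the
combination predictor's held-out AUC and the planted-informative precision
of the final biomarkers are both high (≥ 0.75 / ≥ 0.80 asserted; observed
≈ 0.98 / ≈ 0.92). Problem sizes (400 genes, 60 lines, cohorts of 100, 100–
200 runs) were chosen so each experiment completes in minutes on one CPU
while keeping Monte-Carlo error well inside the asserted tolerances.

## 7. Known limitations

* The combination rule assumes independent drug action; correlated
  responses would call for an estimated weighting.
* Wald intervals behave poorly near 0/1 with tiny n (they are used because
  they are what the validation tables use); Wilson or exact intervals would
  be the modern choice.
* The permutation null conditions on B's observed correlation matrix;
  uncertainty in the correlation estimates themselves is not propagated.
* `cv_accuracy` from a pipeline with an active discovery screen is a
  training-panel quantity (see §3); patient-cohort AUC is the honest
  transfer estimate.
* Progression-free survival and continuous residual-burden endpoints are
  out of scope.
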