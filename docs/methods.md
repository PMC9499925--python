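# Methods

## Problem and model

Pregnancy-associated hypertension (gestational hypertension, preeclampsia,
eclampsia, superimposed preeclampsia) complicates 1–8% of pregnancies, and
early risk identification matters because aspirin prophylaxis works best
when started in the first trimester. Guideline risk-factor rules (at least
one high-risk factor, or at least two moderate-risk factors) have low
sensitivity, and prospective cohorts inevitably contain patients lost to
follow-up whose outcomes are unknown — unusable by supervised learners but
not by a transductive one.

`gravinet` treats each pregnant woman as a node of a weighted patient
similarity network. With standardized clinical variables, the edge weight
between patients *i* and *j* is

    w_ij = exp(-dist(v_i, v_j) / σ²)

where `dist` is the Euclidean distance. Labels are encoded y_i ∈ {+1
(case), −1 (control), 0 (unknown outcome)}, and the predicted score vector
**f** minimizes

    (f − y)ᵀ(f − y) + μ fᵀ L f,      L = D − W,  d_i = Σ_j w_ij

whose closed form is **f** = (I + μL)⁻¹ **y**. The first term anchors
scores to observed labels; the Laplacian term smooths scores across
strongly connected patients; μ > 0 trades the two off. Because (I + μL)
is a symmetric positive-definite M-matrix with unit row sums, its inverse
is nonnegative with unit row sums, so every f_i is a convex combination of
label values and min(y) ≤ f_i ≤ max(y). The linear system is solved by
Cholesky factorization; no explicit inverse is ever formed, and one
factorization back-solves arbitrarily many label columns (used heavily in
cross-validation). Patients are classified by the threshold that maximizes
Youden's J = sensitivity + specificity − 1 on the labeled training nodes.

The model is transductive: new patients are scored by rebuilding the
network over the union of fitted and new nodes with the new labels set
to 0 (`GraphSSLClassifier.decision_function` does exactly this).

## Feature selection

Variables are ranked by four multivariate methods — recursive feature
elimination around a linear SVM and around logistic regression (one
variable removed per retrain), and random-forest impurity importance under
the Gini and entropy criteria (500 trees, fixed seed) — and combined into
an integrated ranking by the element-wise geometric mean
(∏ r_i)^(1/n). Ties are broken by variable name for reproducibility.
Backward elimination then removes the worst integrated-rank variable one
at a time, scores every remaining subset by cross-validated AUROC of the
propagation model, and keeps the subset at the global maximum (the first,
i.e. largest, subset on ties). Linear models see standardized inputs;
forests take raw inputs, being scale-invariant.

## Evaluation protocol

The cohort is split chronologically: the earlier enrollment era is the
training set, the later era the test set. Hyper-parameters (σ, μ) are
tuned by stratified 5-fold cross-validation repeated R times on the
training set; in each fold the validation patients' labels are masked to
0, the network is built over **all** training patients (labeled and
unlabeled), and the masked fold's propagated scores are scored by AUROC.
Repeat r uses stratification seed `base_seed + r`. The σ grid is
scale-adaptive — σ² ∈ {¼, ½, 1, 2, 4} × median pairwise squared distance —
and μ runs over seven log-spaced points in 10⁻³…10³, covering the identity
(μ→0, f→y) and flat (μ→∞, f→mean(y)) limits.

Default R is 10 repeats for desk-scale runs; the CLI's `--full` flag
raises it to 100. The acceptance script uses 10 replicate cohorts of
n = 1404 with 10 CV repeats each, problem sizes chosen so a full run
completes in a couple of minutes on one core.

Test-set metrics: AUROC (Mann–Whitney, ties ½), sensitivity/specificity/
PPV/NPV at the training-derived Youden threshold (prediction positive
strictly above the threshold, so a score of exactly 0 — e.g. an isolated
node — classifies negative). Paired model comparisons use the DeLong
placement-value test on identical test patients and a paired t-test over
per-repeat CV AUROCs sharing fold seeds (zero-variance differences are
reported as p = 1 with a warning). Descriptive group tables use Welch's
t-test for continuous variables and the chi-squared test for binary ones,
switching to Fisher's exact test when any expected cell count is below 5.

## Synthetic cohort generator

No public version of the original cohort exists, so the generator emulates
its printed statistics and is itself first-class, tested code:

- **Group-conditional marginals.** Each of the 11 clinical variables is
  drawn from its per-outcome-group Gaussian (mean, SD) as tabulated for
  the training population (e.g. early-pregnancy systolic BP 113.3 ± 11.4
  control vs 132.7 ± 17.2 case); the history-of-preeclampsia flag is
  Bernoulli (7/949 control, 2/22 case). Outcomes are Bernoulli with
  prevalence 33/1347 ≈ 2.45%.
- **Dependence.** The four blood-pressure measures are pairwise correlated
  (r = 0.7) and the weight/BMI block across eras at r = 0.9 — clinically
  coherent defaults, configurable, with positive semi-definiteness
  checked. BMI is drawn jointly with weight at its own tabulated marginal
  rather than computed from a latent height: computing BMI = weight/height²
  from an independent height would shift the BMI mean by ≈ +0.2 kg/m² and
  inflate its SD (E[1/H²] ≠ 1/E[H]²), breaking the calibration the tests
  verify; the joint-Gaussian construction keeps marginals exact while the
  implied height 100·√(weight/BMI) stays plausible.
- **Missingness.** A fraction 57/1404 of patients, chosen uniformly at
  random, has labels masked to 0 — missing completely at random, matching
  the original report of no significant differences between followed and
  lost patients.
- **Risk flags.** Chronic hypertension, pregestational diabetes, renal and
  autoimmune disease and nulliparity are sampled at their per-group
  baseline-table prevalences; previous preeclampsia mirrors the history
  column; age ≥ 35 and BMI > 30 are thresholded from the generated
  columns, not sampled. Because real age and BMI distributions are
  right-skewed, Gaussian tails understate the threshold-flag prevalences
  (P(age≥35) ≈ 25% vs the observed 29.3%; P(BMI>30) ≈ 1.5% vs 5.3%), so
  the either-criterion flag rate of the synthetic cohort is validated
  against the rate implied by the generator's own parameters, not against
  the real cohort's counts.
- **PlGF.** Log-normal, with the case log-mean 0.5 log-SD below the
  control log-mean (log-SD 0.6, control median 350 pg/mL). The original
  study prints no PlGF distribution, only that case levels are lower, so
  the implied biomarker AUROC Φ(0.5/√2) ≈ 0.64 is a configurable design
  choice, not a reproduction target.
- **Distractors.** Optional standard-normal, outcome-independent columns
  standing in for the non-tabulated members of the routine variable pool,
  to exercise feature selection.
- **Era tags.** The first 971/1347 of the cohort (by row order) is tagged
  as the training era, so labeled era counts match the 971/376 split in
  expectation while unlabeled patients also carry a tag.

What passing tests on this generator do **not** show: robustness to skewed
or heavy-tailed marginals, informative (outcome-dependent) follow-up loss,
measurement error, cross-era distribution drift, or real between-variable
dependence beyond the imposed blocks.

## Numerical choices and conventions

- Standardization: location = mean, scale = population SD (ddof 0) of the
  labeled training patients; zero-variance columns are rejected, missing
  values are rejected rather than imputed (the original analysis excluded
  such patients). The few-label biomarker experiment standardizes over the
  whole node set because a ~90-patient reference often leaves a rare
  binary flag constant; no outcome information is involved either way.
- Kernel: the default `linear` mode uses the plain Euclidean distance in
  the exponent, exactly as the weight formula is written; the conventional
  squared-distance RBF is available as `distance_mode="squared"`. The two
  differ only in how σ rescales distances, and σ is tuned, so downstream
  conclusions do not depend on the choice.
- Youden threshold: candidates are midpoints between consecutive sorted
  unique scores, first maximum on ties, with J values within 1e-12 of the
  maximum counted as tied so floating-point noise cannot flip the
  tie-break.
- Class-mass normalization of the ±1 labels is available
  (`balance_classes=True`) but off by default, matching the method as
  published.
- Degenerate inputs raise: single-class labels, non-finite features,
  σ ≤ 0, μ ≤ 0, empty reference subsets.

## A note on the permutation null

With 2.4% prevalence, the propagated score carries a strong unsupervised
component: atypical patients connect weakly to the control-dominated mass
and their scores sit nearer 0 than the bulk's strongly negative scores, so
graph centrality alone ranks cases highly. Label-permutation nulls
therefore concentrate near the real AUROC (≈ 0.95 on default synthetic
cohorts) rather than 0.5, with very small spread. The power check "mean
test AUROC exceeds 0.5 by ≥ 3 permutation-null SDs" consequently passes by
an enormous margin; the acceptance script reports the null mean alongside
so the z-value is interpretable. On data where cases are not feature-space
outliers this unsupervised component would vanish and the label
information would carry the performance.

## Known limitations

- Transductive only: scoring new patients is O(n³) in the rebuilt network;
  no inductive approximation is provided.
- Dense solves limit comfortable cohort sizes to a few thousand patients;
  k-NN sparsification is available but the solver remains dense.
- The generator's Gaussian marginals make guideline threshold flags
  (age ≥ 35, BMI > 30) rarer than in the real cohort (see above).
- Real-cohort headline AUROCs depend on private data and are not
  reproduction targets of this package.
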