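# Methods

## Pipeline model and assumptions

The pipeline treats biomarker discovery as four chained inferences over a
shared gene universe.

**1. Differential expression (per cohort).** Expression is assumed to be a
normalized log2-scale matrix (the scale RMA-style summarization produces);
the package does not process raw probe data. The two-group comparison is a
pooled (equal-variance) linear model. Because cohorts of this design are
small (as few as 3 samples per phenotype), per-gene variances are unstable;
they are moderated by an empirical-Bayes hierarchical model in which the
s²_g are scaled inverse-χ² draws around a prior s₀² with d₀ prior degrees
of freedom. Hyperparameters are estimated by method-of-moments on
log s²_g: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),

* Var(e) − ψ′(d_g/2) > 0 → d₀ = 2·ψ′⁻¹(Var(e) − ψ′(d_g/2)), and
  s₀² = exp( mean(e) + ψ(d₀/2) − log(d₀/2) );
* otherwise the log-variances show no excess dispersion and d₀ = ∞
  (complete shrinkage).

ψ′⁻¹ is inverted by Newton iteration. The moderated t has d_g + d₀ df
(normal in the d₀ = ∞ limit). On shared input this estimator agrees with
the Bioconductor eBayes reference to machine precision (a cross-check in
the test suite holds it to within 10% relative on p-values, the documented
deviation tolerance; observed agreement is ~1e-13).

A DEG must pass BH-adjusted p < 0.05 **and** |log2FC| ≥ log2(2). Fold
change is the difference of group means on the log2 scale. The
meta-analysis is intersection by gene id across all cohorts; membership
ignores direction (directions are recorded per cohort and conflicts
flagged) because the downstream network statistics consume significance,
not sign.

**2. Over-representation.** One-sided hypergeometric tail
P(X ≥ overlap) against user-supplied gene-set collections (GMT), each set
intersected with the measured universe first; BH across sets, adjusted
p < 0.01. Pathway databases are inputs, never fetched.

**3. Network projection.**
*Hubs:* the sub-network is the induced subgraph on the common DEGs plus
their first neighbors (neighbor–neighbor edges included — the standard
first-neighbor semantics of interactive network tools; the alternative
star-only semantics cannot be distinguished from published node/edge
counts and induced is the more common default). Hubs are the union of
top-k by degree and top-k by unnormalized betweenness (endpoints
excluded); normalization cannot change top-k membership, only reported
values. Ties at rank k break by the other metric, then lexicographic id —
a package decision, made deterministic because the upstream convention is
unstated.
*Reporters:* the reporter-features construction. Gene-level input is the
per-cohort **unadjusted** p-value combined across cohorts by Fisher's
method (the combination rule is a package decision; Stouffer or
single-cohort input are trivial substitutions since the scorer takes any
per-gene p vector). Z_g = Φ⁻¹(1 − p_g) with p clamped to [1e−15, 1−1e−15];
feature score Σ Z/√k; background correction subtracts the Monte-Carlo mean
and divides by the Monte-Carlo sd of same-size random gene sets drawn
without replacement from the **whole measured-gene** Z pool (the
background must represent the transcriptome, not the DEG list). Moments
are cached per k with a per-k child seed, so results do not depend on
evaluation order. One-tailed p = 1 − Φ(Z_corr), BH across features,
significant at adjusted p < 0.001. The Methods-style adjusted threshold is
the default; a raw-p threshold is available as a flag since published
wording is ambiguous between the two.

**4. Pre-clinical validation.** Diagnostic AUC is the rank-based
Mann–Whitney probability (ties count ½) and is orientation-maximized,
max(AUC, 1 − AUC), so down-regulated markers are screened symmetrically
with up-regulated ones; the orientation is reported. Threshold AUC ≥ 0.70.
Prognostic screening standardizes each gene (per-sd β) — configurable —
fits the univariate Cox partial likelihood with Breslow tie handling by
Newton-Raphson (|Δβ| < 1e−8, ≤100 iterations, divergence guard at
|β| > 50), splits at the **median** prognostic index (ties to low risk;
the published cut point is unstated, median is the common default), and
compares groups by the log-rank test with O/E accumulated over event
times. The hazard ratio is deliberately the mortality-rate ratio
(O₁/E₁)/(O₂/E₂), not exp(β̂); the two agree within ~15% under proportional
hazards with ≥100 events (a tested property), but the O/E form is the
definition reported. Genes whose fit fails (constant expression, no
events, separation) become NA rows rather than aborting the screen.

**5. Candidates and classification.** Biomarker candidates are biomolecules
(hubs ∪ significant reporter TFs ∪ significant reporter receptors) flagged
diagnostic OR prognostic — the union, not the intersection. Novelty is a
case-insensitive membership check against a local known-gene list; with no
list supplied everything is reported novel with a warning. The
classification harness does its own stratified fold assignment (a pure
function of labels, fold count and seed) and computes accuracy/recall/F1
natively from confusion counts; learners are pluggable sklearn-style
factories. Shipped backends: KNN, decision tree, random forest, gradient
boosting, MLP, XGBoost, LightGBM. Stratified 5-fold is the default scheme
(the published protocol is unstated); the positive class is "case" for
diagnosis and "dead" for vital status.

## Synthetic study generator

The generator emulates the study design, not microarray physics: log2
expression with per-gene baselines Uniform(4, 12), planted DEGs shifted by
±effect in cases (sign Bernoulli(0.5) per gene, shared across cohorts, so
cross-cohort directions are consistent), i.i.d. Gaussian noise. The PPI
network is preferential-attachment (scale-free, connected); bipartite
regulator networks draw each feature's 5–20 targets uniformly, except
planted-active features which draw a fraction `enrichment` from the DEG
set and the rest uniformly (so enrichment = 0 is an exact null). The
validation cohort also measures the regulators themselves, with the
planted-active ones carrying the case shift — regulators are genes too,
which is what makes their downstream diagnostic validation meaningful.
Survival times are exponential with rate h₀·exp(β·x_standardized) and
independent Uniform(0, c_max) censoring.

Default study conditions, chosen once: 3 cohorts × (30 case, 10 control)
— the 3:1 case:control ratio of the motivating cohorts at desk scale —
2000 genes, 5% planted DEGs, effect |log2FC| = 2, noise sd 0.5; validation
100/30; h₀ = 1/1000 day⁻¹, censoring to 2000 days (≈45% censoring);
prognostic β = 1 per sd. Effect and noise defaults are set for clear test
power, since the motivating study publishes no effect-size or variance
parameters.

What the generator does **not** emulate: probe-level effects, batch or
platform differences between cohorts, correlated co-expression structure,
informative censoring, and identifier aliasing. Passing tests therefore
demonstrate correctness of the statistics and the plumbing under a clean
generative model — not robustness to the messiness of real cohorts.

## Numerical choices

* BH adjustment is the standard step-up with monotone enforcement
  (max-rank convention for ties), capped at 1.
* p-clamping before Φ⁻¹ uses ε = 1e−15; Z stays finite for p ∈ {0, 1}.
* Background sampling without replacement uses vectorized rejection when
  k(k−1)/2N < 0.5 and chunked random-key argpartition otherwise; σ_k = 0
  (degenerate pool) is an error, n_samples ≥ 1000 is enforced, default
  100 000 (Monte-Carlo error on Z_corr ≈ 0.005 at k = 10).
* Cox: zero-variance covariates and event-free inputs are errors;
  all-tied prognostic indices put every sample in the low-risk group,
  which the downstream log-rank reports as an error.
* All generators and samplers take explicit integer seeds; child streams
  are derived with SeedSequence so no stage's randomness depends on
  another's consumption.
* Manifest and all tables are written with fixed float formatting, sorted
  keys and no timestamps; a rerun of the same config is byte-identical.

## Problem sizes

The shipped analyses and tests run the study at 2000 genes, 40-sample
cohorts and a 130-sample validation cohort, with 50-replicate simulations
for coefficient-recovery checks and 200-replicate nulls for calibration
checks — sizes at which the full pipeline completes in seconds while every
statistical property (calibration, recovery, conservation laws) is
measurable with comfortable margins.

## Known limitations

* Identifier matching is exact (whitespace-trimmed) string equality;
  probe-to-gene collapsing and symbol aliasing belong to a real-data
  loader, and the collapse policy for multi-probe genes (max-variance is
  the usual guess) is not part of the published record.
* The O/E hazard ratio is undefined when a group has zero expected
  deaths; it is reported as ∞/0 with a warning rather than an error.
* Reporter scoring is one-tailed significance aggregation; it does not
  decompose regulators into up- and down-acting target sets.
* The Cox screen is univariate by design; confounding between correlated
  candidates is not modeled.
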