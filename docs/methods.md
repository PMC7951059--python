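# Methods

This note documents the models and procedures implemented in
`mycnimmune`, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical conventions that matter
for reproducing results.

## Cohort model and preprocessing

The pipeline's universal input is a genes × samples matrix of log2
expression with per-sample clinical annotations (MNA status, survival
time/event, stage). Preprocessing follows standard microarray practice:
quantile normalization across samples (every column is mapped onto the
mean empirical distribution, average-rank ties), replicate probes sharing
a gene label replaced by their mean, then per-gene z-scaling.
Zero-variance genes scale to 0 with a warning rather than an error, so a
platform's flat control probes do not abort a run. Genes with any missing
value are dropped with a logged count — the simplest defensible
missingness policy for array data; no imputation is attempted.

Gene identifiers match exactly (case-sensitive, whitespace-trimmed). No
alias resolution is performed: silent aliasing changes gene counts in
ways that are very hard to audit.

## Differential expression

Two-group comparison with empirical-Bayes variance moderation: per-gene
residual variances s² (df d = n₁+n₂−2) are shrunk toward a prior s₀² with
d₀ degrees of freedom, s̃² = (d₀s₀² + d s²)/(d₀+d), the moderated t uses
d₀+d df, and (d₀, s₀²) are estimated by moment-matching on log s² (the
trigamma inversion of the scaled inverse-chi-square hierarchy). When the
observed spread of log-variances does not exceed the sampling component,
d₀ = ∞ and all genes share the pooled variance. `prior_df=0` disables
shrinkage and reproduces the ordinary two-sample t exactly, which is the
closed-form limit the unit tests pin down. Multiplicity is handled with
Benjamini–Hochberg.

## Preranked enrichment

The enrichment score is the signed maximum deviation of the weighted
running statistic: hits increment by |r|^p / Σ|r|^p (exponent p = 1 by
default), misses decrement by 1/(N − N_hit). Ties in |running| — which
occur when a symmetric +x/−x pair of peaks arises — break to the earliest
list position, with a 1e-12 tolerance so the choice is independent of
floating-point accumulation order. Ranking ties break by gene label, so
ranked lists are fully deterministic.

Significance uses random same-size gene-position sets (gene-label
permutation): NES = ES / mean(|null ES| of the same sign), the nominal p
is the one-sided fraction of same-sign null ES at least as extreme, and
the FDR q follows the positive/negative pooled-null procedure (all null
ES are NES-normalized per set, pooled across sets, and the tail ratio of
null to observed NES is taken, clipped to [0,1]). Set-size bounds 15/500
and exponent 1 are the conventional tool defaults; they are recorded in
the run log because they are assumptions, not published parameters.

## Deconvolution

The signature matrix is built from reference profiles by a one-vs-rest
two-sample t-test per cell type on log2(x+1) (BH q < 0.3 within type),
keeping the top 50 genes by linear fold change per type; the signature is
the per-type mean reference profile over the union of selected genes, and
its condition number is logged as a diagnostic.

Fractions are estimated per sample on the **linear** scale (deconvolution
is linear in cell content): the z-scored mixture is regressed on the
z-scored signature by linear-kernel ν-SVR over ν ∈ {0.25, 0.5, 0.75},
keeping the fit with the highest Pearson correlation; negative
coefficients are clipped to zero and the rest renormalized to sum 1
(relative fractions). A non-negative least squares solver on the raw
linear scale is available as `method="nnls"`; the two engines agree
within 0.05 RMSE on noiseless mixtures and cross-validate each other in
the tests. Per-sample significance is a permutation test: the null fit
correlation is built once per cohort from `n_perm` pseudo-mixtures
resampled (with replacement) from the pooled mixture values and shared
across samples — per-sample nulls would multiply cost by the cohort size
without changing calibration. The default permutation count is 1,000;
tests and the acceptance script use 200 to keep single-CPU runtimes in
minutes (the calibration checks are unaffected at that resolution).

Group comparisons of fractions use the Mann–Whitney rank-sum test: the
MNA and non-MNA groups are independent and of unequal size, so a paired
test is not applicable.

## Surface-protein immune network

A protein counts as cell-surface only with an *approved* or *supported*
annotation to plasma membrane, cell junctions or focal adhesion sites; a
protein counts as expressed in an immune population only with a
normalized score **strictly** greater than 1.5, and only if surface; and
interactions are kept with a combined score **strictly** greater
than 400. "Higher than" is read literally as strict inequality for both
thresholds, and both boundaries are unit-tested. Tumor-side gene lists
come from MNA vs non-MNA differential expression at |logFC| ≥ 0.5
(deliberately permissive, to capture weak interactions), or from
TF-knockdown differential lists at |logFC| ≥ 1 (down on knockdown =
positively regulated), both intersected with the surface set.

Edge tables are deduplicated to undirected edges (keeping the maximum
score of bidirectional rows) **before** the score filter, and self-loops
are dropped at load. The network annotates each (unordered pair,
population) once; a pair whose endpoints both qualify as tumor-side and
population-side contributes one edge per orientation. Counts exported for
circular plots: edges per population, edges per (tumor gene, population),
and shared tumor–immune pairs per population pair. The filters commute —
the cascade yields the same network in any order — and the implementation
is checked edge-for-edge against a brute-force oracle on fixtures.

## Co-expression modules

Signed weighted network at the published parameters: adjacency
a_ij = ((1 + cor)/2)⁸, unsigned topological overlap
ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), dissimilarity 1 − ω,
average-linkage hierarchical clustering, minimum module size 20.

Branches are cut at a fixed dissimilarity height (default 0.90) and
clusters below the minimum size are left unassigned (module 0). The
static cut was chosen over an adaptive branch-shape heuristic because on
TOM dissimilarity the relevant structure is a gap, not a gradient:
correlated blocks complete their merges well below ~0.85 while unrelated
genes attach near 1, so a cut in the gap recovers planted modules exactly,
leaves pure-noise cohorts essentially unassigned, and is deterministic
and easy to reason about. The height is exposed (`cut_height`) for data
where the gap sits elsewhere. Modules are numbered by decreasing size.

Eigengenes are the first right singular vector of the module's
gene-standardized expression, scaled to unit variance and sign-oriented
so the correlation with the module's mean profile is non-negative;
single-gene modules degenerate to that gene's z-scores. No module merging
by eigengene similarity is performed — the similarity matrix is reported
instead so the analyst can see near-duplicate modules. Module–trait
profiles are group means of eigengenes z-scored across groups (for two
groups these are exact ±z pairs); population composition is the count of
each population's proteins per module, z-scored per population row; set
enrichment is the hypergeometric upper tail over the clustered-gene
background, BH-adjusted.

## Regulons

Regulators are inferred by module-wise over-representation of each TF's
target set (hypergeometric, BH across all TF × module pairs; TFs with
q < 0.05 in ≥ 1 module are selected). The TF → target prior is an
explicit input so a richer inference method can be substituted; the
statistic here is the minimal published-practice reading of inferring
regulators from gene modules. The prior's gene universe should match the
clustering universe — mismatched universes make random target sets look
enriched. Regulon activity is the mean of target gene z-scores per
sample, row-z-scored (hence invariant to shifting any target by a
constant); regulons and patients cluster hierarchically on Euclidean
distance with average linkage (the heatmap caption convention fixes only
the metric; average linkage is our default and is stated in outputs).
Consensus regulons across cohorts are the TF-label intersection of the
selected lists with both cohorts' statistics retained.

## The MYCN immune score

*MNA arm.* L1-penalized logistic regression (inverse strength C = 0.1) of
MNA status on immune-gene expression, refit over 50 Monte-Carlo
subsampling rounds (stratified random 80% train / 20% test; "50-fold at
80%" can only be Monte-Carlo subsampling, since 50 disjoint folds
contradict an 80% training share). Per-gene weights are averaged over
rounds with zeros included; genes averaging exactly zero are dropped.
The liblinear coordinate-descent solver is used — the contract is the
penalized optimum, not a specific optimizer — seeded per round for byte
reproducibility. Held-out AUC is reported per round.

*Survival arm.* A univariate Cox screen (own vectorized Newton solver on
the Breslow partial likelihood, genes standardized; validated against
lifelines on small data) with Bonferroni correction at α = 0.05/m, then
an L1-penalized multivariate Cox fit at a fixed penalty λ₁ = 0.25 via
coordinate descent (scikit-survival's coxnet). λ₁ follows the
penalized-likelihood convention (penalty on the unscaled log partial
likelihood) and is rescaled by the sample count for the solver, whose
penalty multiplies the per-sample likelihood. λ₁ = 0 reproduces the
unpenalized multivariate fit to 1e-3.

*Fusion.* Each of the four weight vectors is min–max normalized to [0,1].
Negative-orientation vectors (W^NM, W^NC) are sign-flipped **before**
normalization so that the strongest non-MNA/protective gene maps to 1;
without the flip, min–max would invert the ordering so that the weakest
protective gene dominates the negative score. `negate_negative=False`
preserves the literal alternative. The positive signature is the
intersection of the MNA-positive and hazard-positive gene sets with
weight Ŵ^PM + Ŵ^PC (the negative signature analogously); the per-patient
sub-scores are weighted mean log2 expressions, the score is their ratio,
and strata are cut on the cohort z-score of the ratio at −0.5 and 1
(both boundaries belong to the medium stratum). The z-score is computed
within the scored cohort — each dataset is normalized on its own, so
scores are comparable within but not across cohorts. Scoring a cohort
missing signature genes proceeds over the present genes with the
denominator reduced, warns about the coverage, and errors below 80%
coverage; a non-positive immN signals a wrong expression scale (e.g.
ratio or centred data) and is an error.

A note on attainable recovery: when many planted genes share the group
axis and the overall hazard range is bounded, their *conditional*
per-gene Cox effects are necessarily small, and an L1 multivariate fit
will zero or sign-flip part of such a redundant block at any sample size
a desk study can simulate. The meaningful end-to-end property — which the
acceptance checks measure — is therefore the *composition* of the final
signature (planted-concordant fraction, noise contamination) and its
downstream behaviour (stratum hazard separation, held-out AUC), not
per-gene recall over the redundant block.

## Survival statistics

Kaplan–Meier product-limit curves per stratum with the k-sample log-rank
test; multivariate Cox proportional-hazards fits with Efron tie handling
(HR, 95% CI, Wald p per covariate); overall and event-free survival share
one code path parameterized by which clinical columns supply (time,
event). Panel correlations (checkpoints, MHC, TLRs, cytokines) are
per-gene Pearson r against the score z, BH-adjusted, with missing panel
genes reported. These stages delegate to lifelines; the pipeline's own
contributions are the strata and the score.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` draws per-gene baselines N(7, 1.5²) on the log2 scale
(typical array intensity range), adds the planted group effects (defaults:
60 genes +1.5 log2 units in MNA, 40 genes +1.5 in non-MNA, at an MNA
fraction of 0.2 — matching the roughly one-in-five MNA prevalence of
neuroblastoma cohorts), one additive Gaussian latent factor per
configured module, and N(0, 1) noise. Survival is exponential
proportional hazards on the planted-gene linear predictor Σβ_g·(centered
x_g), centred and unit-scaled by default so hazard ratios stay in a
clinically plausible range, with independent exponential censoring
(baseline hazard 0.1/unit, censor rate 0.05 → roughly one-third events).
Stage is sampled with MNA tumours enriched for stage 4. Mixing fractions
for deconvolution are Dirichlet(1,…,1) — exactly the uniform simplex —
with 5 cell types × 40 disjoint markers (high/low contrast 500/20 on the
linear scale) and 5% multiplicative noise. One integer seed feeds
spawned, independent sub-streams per generator, so every artifact is
byte-reproducible.

Deliberately **not** modelled: probe-level microarray effects, batch
effects, heavy-tailed or count-like noise, correlated censoring,
overlapping marker genes between cell types, and real neuroblastoma
expression marginals beyond log-normality. Passing tests therefore
demonstrate correctness of the algorithms under the planted model and
calibration of the statistics under clean nulls — not performance on any
particular real cohort.

## Problem sizes and defaults used in tests and the acceptance script

Signature derivation runs on 600 samples × 2,000 genes with 50 logistic
rounds; module recovery on 300 × 300 with four planted factors (5 seeds);
deconvolution on 40 mixtures of 5 types at 200 permutations; GSEA
calibration on 500 random sets at 200 permutations; Cox-screen error on
200 null cohorts of 150 × 200. These sizes make the statistical claims
testable in minutes on one CPU while leaving every algorithmic path
identical to a full-size run.

## Known limitations

- The tree cut is global-height based; modules separated by branch shape
  at a shared height (rare on TOM, common on raw correlation) need the
  `cut_height` adjusted.
- The regulon statistic tests target–module overlap only; it does not use
  expression directionality or TF expression itself.
- The deconvolution permutation null assumes exchangeability of pooled
  mixture values; strongly structured cohorts (e.g. severe batch shifts)
  would need a stratified null.
- The score's ratio form requires non-negative log2 expression; cohorts
  distributed as ratios or z-scores must be re-anchored before scoring.
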