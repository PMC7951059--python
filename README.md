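# mycnimmune

Tools for analysing how *MYCN* amplification (MNA) reshapes the tumor
immune landscape in neuroblastoma bulk expression cohorts, and for
deriving the composite **MYCN immune score** that stratifies patients by
immune dysregulation and prognosis.

The package is aimed at computational biologists working with two-group
(MNA vs non-MNA) log2 expression cohorts plus clinical survival tables.
It provides, as composable library stages with a thin CLI:

- **Preprocessing & ranking** — quantile normalization, replicate-probe
  averaging, per-gene scaling; Pearson ranking against a driver gene
  (*MYCN*/*MYC*); moderated-t differential expression (empirical-Bayes
  variance shrinkage, BH adjustment).
- **Preranked GSEA** — weighted Kolmogorov–Smirnov enrichment score,
  gene-label permutation null, NES, and the positive/negative pooled-null
  FDR.
- **Immune-cell deconvolution** — signature-matrix construction from
  reference profiles (one-vs-rest selection) and per-sample fraction
  estimation by linear ν-SVR with an NNLS fallback and a permutation
  significance test; rank-sum group comparison of fractions.
- **Surface-protein immune network** — the filter cascade (reliable
  surface location; population score > 1.5; interaction score > 400;
  DE assignment at |logFC| ≥ 0.5, knockdown lists at |logFC| ≥ 1) and the
  bipartite tumor-gene ↔ immune-population network with counts for
  circular plots.
- **Co-expression modules** — signed adjacency ((1+r)/2)⁸, topological
  overlap, average-linkage module detection (min size 20), eigengenes,
  module similarity, module–trait z-profiles, population composition and
  hypergeometric set enrichment.
- **Regulons** — module-wise TF target over-representation against a
  prior, mean-z target activity, 3-cluster regulon structure, cross-cohort
  consensus.
- **MYCN immune score** — the core model (below) plus Kaplan–Meier /
  log-rank stratum validation, multivariate Cox independence and panel
  correlations.
- **Synthetic cohorts** — a simulator planting group effects,
  proportional-hazards survival, co-expression factors, mixing fractions
  and regulon priors with full ground truth, so the whole pipeline runs
  and is tested without any external downloads.

## The MYCN immune score

On the immune-gene expression of a training cohort, two penalized models
are fitted:

1. **MNA model.** L1 logistic regression of MNA status (C = 0.1), refit on
   50 random 80/20 subsamples; per-gene weights averaged, exact zeros
   dropped. Positive averages form W^PM, negative W^NM.
2. **Survival model.** Bonferroni-corrected univariate Cox screen, then an
   L1-penalized multivariate Cox fit (λ₁ = 0.25); positive coefficients
   form W^PC, negative W^NC.

Each vector is min–max normalized, Ŵᵢ = (Wᵢ − min W)/(max W − min W).
Genes present in both same-orientation vectors form the signatures, and
per patient

    immP = (1/n) Σᵢ xᵢ (Ŵᵢ^PM + Ŵᵢ^PC)
    immN = (1/n) Σᵢ xᵢ (Ŵᵢ^NM + Ŵᵢ^NC)
    score = immP / immN

with x the log2 expression. Patients are stratified on the cohort z-score
of the ratio: **low** (z < −0.5), **medium** (−0.5 ≤ z ≤ 1), **high**
(z > 1).

## Worked example

```python
from mycnimmune import MycnImmuneScore
from mycnimmune.simulate import CohortConfig, generate_cohort
from mycnimmune.survival import kaplan_meier_logrank

cohort, truth = generate_cohort(CohortConfig(n_samples=600, n_genes=2000, seed=1))
expr, clin = cohort["expression"], cohort["clinical"]

model = MycnImmuneScore(n_rounds=50, random_state=1)
scores = model.fit_transform(expr, clin["mna_status"],
                             clin["surv_time"], clin["surv_event"])
print(scores["stratum"].value_counts().to_dict())
print(f"mean held-out AUC: {sum(model.auc_rounds_)/len(model.auc_rounds_):.3f}")

sel = scores["stratum"].isin(["high", "low"])
_, test = kaplan_meier_logrank(scores.loc[sel, "stratum"],
                               clin.loc[sel, "surv_time"],
                               clin.loc[sel, "surv_event"])
print(f"log-rank high vs low: p = {test['p']:.2e}")
```

prints

```
{'medium': 245, 'low': 235, 'high': 120}
mean held-out AUC: 1.000
log-rank high vs low: p = 8.84e-71
```

The simulated cohort plants 60 MNA-up/hazardous and 40 non-MNA-up/
protective genes; the derived signature is built only from those plants
(the MNA separation is easy at the planted effect size, hence the AUC),
and the high stratum carries a markedly worse planted hazard than the low
stratum, which the log-rank test picks up.

The same pipeline runs from the shell:

```bash
mycn-immune all --out results/ --seed 1 --n-samples 300 --n-genes 600
mycn-immune simulate --config cohort.yaml --out sim/
mycn-immune score --expression sim/expression.tsv --clinical sim/clinical.tsv --out scored/
```

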