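"""The MYCN immune score: signature derivation and patient scoring.

The signature fuses two penalized models fitted on the immune-gene
expression of a training cohort:

* an L1 logistic regression of MNA status (C = 0.1), refitted over 50
  random 80/20 subsampling rounds with per-gene weights averaged and
  exact zeros dropped -> MNA-positive (W^PM) and MNA-negative (W^NM)
  weight vectors;
* a Bonferroni-screened univariate Cox pass followed by an L1-penalized
  multivariate Cox fit (lambda1 = 0.25) -> hazard-positive (W^PC) and
  hazard-negative (W^NC) vectors.

Each vector is min-max normalized to [0, 1]; genes present in both the
MNA and the Cox vector of the same orientation form the positive /
negative signatures with weight Ŵ^PM + Ŵ^PC (resp. Ŵ^NM + Ŵ^NC).  Per
patient, immP and immN are the weighted mean log2 expressions over the
two signatures, the score is immP/immN, and patients are stratified on
the cohort z-score of the ratio at -0.5 and 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger("mycnimmune")

__all__ = [
    "fit_mna_logistic",
    "univariate_cox_screen",
    "penalized_cox",
    "minmax_normalize",
    "combine_weights",
    "compute_scores",
    "stratify",
    "MycnImmuneScore",
]


def fit_mna_logistic(
    expr_immune: pd.DataFrame,
    mna_labels,
    C: float = 0.1,
    n_rounds: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, list[float]]:
    """Subsampled L1 logistic regression of MNA status on immune genes.

    Each round fits on a random stratified ``train_frac`` subsample and
    scores AUC on the held-out rest; weights are averaged over rounds
    (zeros included) and genes with an exactly zero average are dropped.
    Returns ``(w_pm, w_nm, auc_per_round)`` with ``w_pm`` the positive
    averaged weights and ``w_nm`` the (negative-valued) negative ones.
    """
    y = np.asarray(mna_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both MNA classes must be present")
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    X = expr_immune.to_numpy(dtype=float).T
    rng = np.random.default_rng(seed)
    coefs = np.zeros((n_rounds, X.shape[1]))
    aucs = []
    for r in range(n_rounds):
        round_seed = int(rng.integers(2**31 - 1))
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=round_seed
        )
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000,
            random_state=round_seed,
        )
        model.fit(Xtr, ytr)
        coefs[r] = model.coef_.ravel()
        aucs.append(float(roc_auc_score(yte, model.decision_function(Xte))))
    avg = pd.Series(coefs.mean(axis=0), index=expr_immune.index)
    avg = avg[avg != 0.0]
    return avg[avg > 0], avg[avg < 0], aucs


def univariate_cox_screen(
    expr_immune: pd.DataFrame,
    surv_time,
    surv_event,
    alpha: float = 0.05,
    return_table: bool = False,
):
    """Bonferroni-screened single-gene Cox proportional-hazards scan.

    Each gene (standardized) is fitted alone by Newton iteration on the
    Breslow partial likelihood, vectorized across genes; genes with Wald
    p <= alpha / n_genes pass.  Returns the screened gene list (or the
    full per-gene table when ``return_table``).
    """
    t = np.asarray(surv_time, dtype=float)
    d = np.asarray(surv_event, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if d.sum() < 20:
        raise ValueError("need >= 20 events for the Cox screen")

    x = expr_immune.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d zero-variance genes skipped in Cox screen",
                       int((~keep).sum()))
    genes = expr_immune.index[keep]
    x = x[keep]
    x = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]

    # sort samples by descending time; ties share the risk set through the
    # end of their tie group (Breslow)
    order = np.argsort(-t, kind="mergesort")
    td, dd, xd = t[order], d[order], x[:, order]
    n = len(td)
    last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and td[j + 1] == td[i]:
            j += 1
        last[i : j + 1] = j
        i = j + 1
    ev = np.flatnonzero(dd == 1)
    ev_last = last[ev]

    beta = np.zeros(len(genes))
    info = np.ones(len(genes))
    for _ in range(25):
        e = np.exp(np.clip(beta[:, None] * xd, -500, 500))
        c0 = np.cumsum(e, axis=1)
        c1 = np.cumsum(xd * e, axis=1)
        c2 = np.cumsum(xd * xd * e, axis=1)
        s0 = c0[:, ev_last]
        s1 = c1[:, ev_last]
        s2 = c2[:, ev_last]
        u = (xd[:, ev] - s1 / s0).sum(axis=1)
        info = (s2 / s0 - (s1 / s0) ** 2).sum(axis=1)
        step = u / np.maximum(info, 1e-12)
        beta = np.clip(beta + np.clip(step, -2.0, 2.0), -50, 50)
        if np.max(np.abs(step)) < 1e-10:
            break
    z = beta * np.sqrt(np.maximum(info, 0.0))
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"beta": beta, "p": p}, index=genes)
    m = len(genes)
    table["pass"] = table["p"] <= alpha / m
    if return_table:
        return table
    return list(table.index[table["pass"]])


def penalized_cox(
    expr_screened: pd.DataFrame,
    surv_time,
    surv_event,
    lambda1: float = 0.25,
) -> tuple[pd.Series, pd.Series]:
    """L1-penalized multivariate Cox at a fixed penalty (no internal tuning).

    ``lambda1`` follows the convention of a penalty on the unscaled
    partial log-likelihood (penalized-likelihood lambda); internally it is
    rescaled by the sample count for the coordinate-descent solver.
    Returns positive (W^PC) and negative (W^NC) nonzero coefficients.
    """
    if expr_screened.shape[0] < 1:
        raise ValueError("no screened genes to fit")
    t = np.asarray(surv_time, dtype=float)
    d = np.asarray(surv_event, dtype=int)
    if d.sum() < 20:
        raise ValueError("need >= 20 events for the penalized Cox fit")
    X = expr_screened.to_numpy(dtype=float).T
    y = Surv.from_arrays(event=d.astype(bool), time=t)
    alpha = max(lambda1, 1e-8) / X.shape[0]
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[alpha], normalize=False, max_iter=100000,
        fit_baseline_model=False,
    )
    model.fit(X, y)
    coef = pd.Series(model.coef_.ravel(), index=expr_screened.index)
    coef = coef[coef != 0.0]
    if coef.empty:
        raise ValueError(
            "penalized Cox selected no genes; try a smaller lambda1"
        )
    return coef[coef > 0], coef[coef < 0]


def minmax_normalize(weights: pd.Series, negate: bool = False) -> pd.Series:
    """Map a raw weight vector onto [0, 1]: min -> 0, max -> 1.

    With ``negate`` the vector is sign-flipped first, so that for
    negative-orientation vectors the strongest (most negative) weight
    maps to 1.
    """
    w = -weights if negate else weights.copy()
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        raise ValueError("constant weight vector: zero range")
    return (w - lo) / (hi - lo)


def combine_weights(pm: pd.Series, pc: pd.Series, nm: pd.Series, nc: pd.Series
                    ) -> tuple[pd.Series, pd.Series]:
    """Sum normalized MNA and Cox weights over the common genes.

    Positive signature: genes in both Ŵ^PM and Ŵ^PC with weight
    Ŵ^PM + Ŵ^PC; negative signature analogously from Ŵ^NM and Ŵ^NC.
    """
    pos_genes = pm.index.intersection(pc.index)
    neg_genes = nm.index.intersection(nc.index)
    if len(pos_genes) == 0 or len(neg_genes) == 0:
        raise ValueError(
            "empty intersection between MNA and Cox weight vectors "
            f"(positive: {len(pos_genes)}, negative: {len(neg_genes)})"
        )
    return (pm[pos_genes] + pc[pos_genes]).sort_index(), (
        nm[neg_genes] + nc[neg_genes]
    ).sort_index()


def compute_scores(
    expr: pd.DataFrame,
    positive_weights: pd.Series,
    negative_weights: pd.Series,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Per-patient immP, immN, ratio score, cohort z-score and stratum.

    immP = (1/n) sum_i x_i * w_i over the positive-signature genes present
    in the cohort (immN analogously); x is log2 expression (>= 0).  Score
    computation fails below ``min_coverage`` signature-gene presence, or
    if any patient's immN is non-positive (wrong expression scale).
    """
    out = {}
    for name, weights in (("immP", positive_weights), ("immN", negative_weights)):
        present = weights.index.intersection(expr.index)
        cov = len(present) / len(weights)
        if cov < min_coverage:
            raise ValueError(
                f"{name}: only {cov:.0%} of signature genes present "
                f"(need >= {min_coverage:.0%})"
            )
        if cov < 1.0:
            logger.warning("%s computed on %.0f%% signature coverage", name, 100 * cov)
        x = expr.loc[present].to_numpy(dtype=float)
        out[name] = (weights[present].to_numpy()[:, None] * x).mean(axis=0)
    immp, immn = out["immP"], out["immN"]
    if (immn <= 0).any():
        raise ValueError(
            "non-positive immN encountered; expression must be non-negative log2"
        )
    score = immp / immn
    z = (score - score.mean()) / score.std(ddof=1)
    table = pd.DataFrame(
        {"immP": immp, "immN": immn, "score": score, "z": z}, index=expr.columns
    )
    table["stratum"] = stratify(table["z"])
    return table


def stratify(z_scores) -> pd.Series:
    """low: z < -0.5; medium: -0.5 <= z <= 1; high: z > 1."""
    z = pd.Series(z_scores)
    out = pd.Series("medium", index=z.index, name="stratum")
    out[z < -0.5] = "low"
    out[z > 1.0] = "high"
    return out


class MycnImmuneScore(BaseEstimator):
    """End-to-end MYCN immune-score estimator.

    ``fit`` derives the signature on a training cohort (expression
    restricted to the immune-gene universe plus MNA labels and survival);
    ``transform`` scores any cohort carrying the signature genes.

    Fitted attributes: ``w_pm_``/``w_nm_`` (raw averaged logistic
    weights), ``screened_genes_``, ``w_pc_``/``w_nc_`` (lasso Cox
    coefficients), ``positive_signature_``/``negative_signature_``
    (combined normalized weights) and ``auc_rounds_``.
    """

    def __init__(self, C=0.1, n_rounds=50, train_frac=0.8, cox_alpha=0.05,
                 lambda1=0.25, negate_negative=True, min_coverage=0.8,
                 random_state=0):
        self.C = C
        self.n_rounds = n_rounds
        self.train_frac = train_frac
        self.cox_alpha = cox_alpha
        self.lambda1 = lambda1
        self.negate_negative = negate_negative
        self.min_coverage = min_coverage
        self.random_state = random_state

    def fit(self, expr: pd.DataFrame, mna_labels, surv_time, surv_event,
            immune_genes=None):
        if immune_genes is not None:
            present = [g for g in immune_genes if g in expr.index]
            expr = expr.loc[present]
        self.w_pm_, self.w_nm_, self.auc_rounds_ = fit_mna_logistic(
            expr, mna_labels, C=self.C, n_rounds=self.n_rounds,
            train_frac=self.train_frac, seed=self.random_state,
        )
        self.screened_genes_ = univariate_cox_screen(
            expr, surv_time, surv_event, alpha=self.cox_alpha
        )
        if not self.screened_genes_:
            raise ValueError("univariate Cox screen selected no genes")
        self.w_pc_, self.w_nc_ = penalized_cox(
            expr.loc[self.screened_genes_], surv_time, surv_event,
            lambda1=self.lambda1,
        )
        pm = minmax_normalize(self.w_pm_)
        pc = minmax_normalize(self.w_pc_)
        nm = minmax_normalize(self.w_nm_, negate=self.negate_negative)
        nc = minmax_normalize(self.w_nc_, negate=self.negate_negative)
        self.positive_signature_, self.negative_signature_ = combine_weights(
            pm, pc, nm, nc
        )
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        return compute_scores(
            expr, self.positive_signature_, self.negative_signature_,
            min_coverage=self.min_coverage,
        )

    def fit_transform(self, expr, mna_labels, surv_time, surv_event,
                      immune_genes=None):
        return self.fit(
            expr, mna_labels, surv_time, surv_event, immune_genes
        ).transform(expr)
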