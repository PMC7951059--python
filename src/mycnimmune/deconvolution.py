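"""Reference-based immune-cell deconvolution.

Builds a cell-type signature matrix from reference profiles (one-vs-rest
differential selection, top genes by fold change) and estimates relative
cell-type fractions in bulk mixtures by linear-kernel nu-support-vector
regression over a small nu grid (the published scheme of the cited
deconvolution tool), with a non-negative least squares fallback.
Per-sample significance comes from a permutation null of pseudo-mixtures
resampled from the cohort's own expression values.

Mixtures and references are on the linear (anti-logged) scale:
deconvolution is linear in cell content.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.svm import NuSVR
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mycnimmune")

__all__ = [
    "build_signature_matrix",
    "estimate_fractions",
    "compare_fractions",
    "Deconvolver",
]


def build_signature_matrix(
    refs: pd.DataFrame,
    type_map: pd.Series,
    top_genes: int = 50,
    q_threshold: float = 0.3,
) -> pd.DataFrame:
    """Select discriminating genes and average reference profiles per type.

    For each cell type, a one-vs-rest two-sample t-test on log2(x+1)
    reference values (BH-adjusted per type); among genes with q below the
    threshold and higher expression in the type, the ``top_genes`` with the
    largest linear fold change are kept.  The signature is the per-type
    mean reference profile over the union of selected genes.
    """
    types = sorted(type_map.unique())
    if len(types) < 2:
        raise ValueError("at least 2 cell types are required")
    logx = np.log2(refs.to_numpy(dtype=float) + 1.0)
    selected: set[str] = set()
    for t in types:
        m = (type_map.reindex(refs.columns) == t).to_numpy()
        if m.sum() < 1:
            raise ValueError(f"cell type {t!r} has no reference samples")
        with np.errstate(invalid="ignore"):
            tstat, p = stats.ttest_ind(logx[:, m], logx[:, ~m], axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        q = multipletests(p, method="fdr_bh")[1]
        mean_in = refs.to_numpy()[:, m].mean(axis=1)
        mean_out = refs.to_numpy()[:, ~m].mean(axis=1)
        fc = (mean_in + 1.0) / (mean_out + 1.0)
        ok = (q < q_threshold) & (fc > 1.0)
        if not ok.any():
            raise ValueError(
                f"no significant genes for cell type {t!r}; "
                "increase top_genes or relax q_threshold"
            )
        idx = np.argsort(-fc * ok)[: min(top_genes, int(ok.sum()))]
        selected.update(refs.index[i] for i in idx if ok[i])
    genes = [g for g in refs.index if g in selected]
    sig = pd.DataFrame(
        {t: refs.loc[genes, type_map.index[type_map == t]].mean(axis=1) for t in types}
    )
    cond = np.linalg.cond(sig.to_numpy())
    logger.info("signature matrix: %d genes, %d types, condition number %.2f",
                sig.shape[0], sig.shape[1], cond)
    sig.attrs["condition_number"] = float(cond)
    return sig


def _solve_sample(y: np.ndarray, X: np.ndarray, method: str, nus) -> tuple[np.ndarray, float]:
    """One-sample deconvolution on z-scored data; returns (raw coefs, fit r)."""
    ys = (y - y.mean()) / (y.std() or 1.0)
    Xs = (X - X.mean()) / (X.std() or 1.0)
    if method == "svr":
        best_coef, best_r = None, -np.inf
        for nu in nus:
            model = NuSVR(nu=nu, C=1.0, kernel="linear")
            model.fit(Xs, ys)
            coef = model.coef_.ravel()
            pred = Xs @ coef
            r = np.corrcoef(pred, ys)[0, 1] if pred.std() > 0 else 0.0
            if r > best_r:
                best_coef, best_r = coef, r
        return best_coef, float(best_r)
    coef, _ = optimize.nnls(X, y)       # raw linear scale; f >= 0
    pred = X @ coef
    r = np.corrcoef(pred, y)[0, 1] if pred.std() > 0 else 0.0
    return coef, float(r)


def estimate_fractions(
    expr: pd.DataFrame,
    sig: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "svr",
    nus: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Estimate relative cell-type fractions for every mixture sample.

    ``expr``: genes x samples linear-scale mixtures; ``sig``: signature
    genes x cell types.  Negative regression coefficients are clipped to
    zero and fractions renormalized to sum 1.  The permutation p-value is
    the fraction of ``n_perm`` random pseudo-mixtures (values resampled
    from the pooled mixture matrix) whose fit correlation reaches the
    observed one; the null is built once and shared across samples.

    Returns samples x types fractions plus ``p`` and ``fit_r`` columns.
    """
    if method not in ("svr", "nnls"):
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    common = [g for g in sig.index if g in expr.index]
    overlap = len(common) / sig.shape[0]
    if overlap < 0.3:
        raise ValueError(
            f"only {overlap:.0%} of signature genes present in the mixture (need >= 30%)"
        )
    X = sig.loc[common].to_numpy(dtype=float)
    Y = expr.loc[common].to_numpy(dtype=float)
    if (Y.sum(axis=0) == 0).any():
        raise ValueError("all-zero mixture sample")

    rng = np.random.default_rng(seed)
    rows, fit_rs = [], []
    for j in range(Y.shape[1]):
        coef, r = _solve_sample(Y[:, j], X, method, nus)
        coef = np.clip(coef, 0.0, None)
        total = coef.sum()
        frac = coef / total if total > 0 else np.full(len(coef), 1.0 / len(coef))
        rows.append(frac)
        fit_rs.append(r)

    pool = Y.ravel()
    null_r = np.empty(n_perm)
    for b in range(n_perm):
        pseudo = rng.choice(pool, size=len(common), replace=True)
        _, null_r[b] = _solve_sample(pseudo, X, method, nus)
    pvals = [(np.sum(null_r >= r) + 1) / (n_perm + 1) for r in fit_rs]

    out = pd.DataFrame(rows, index=expr.columns, columns=sig.columns)
    out["p"] = pvals
    out["fit_r"] = fit_rs
    return out


def compare_fractions(fractions: pd.DataFrame, group_labels) -> pd.DataFrame:
    """Per-type rank-sum comparison of fractions between two groups.

    Returns one row per cell type with group means/medians, the
    Mann-Whitney U statistic, p-value and the direction of enrichment.
    """
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1, g0 = labels == groups.max(), labels == groups.min()
    if min(g1.sum(), g0.sum()) < 3:
        raise ValueError("each group needs at least 3 samples")
    types = [c for c in fractions.columns if c not in ("p", "fit_r")]
    rows = []
    for t in types:
        a = fractions.loc[g1, t].to_numpy()
        b = fractions.loc[g0, t].to_numpy()
        if np.all(fractions[t].to_numpy() == fractions[t].iloc[0]):
            logger.warning("cell type %s has constant fractions; p set to 1", t)
            u, p = np.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "cell_type": t,
                "mean_group1": a.mean(), "mean_group0": b.mean(),
                "median_group1": float(np.median(a)),
                "median_group0": float(np.median(b)),
                "U": u, "p": p,
                "direction": "group1" if a.mean() >= b.mean() else "group0",
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


class Deconvolver(BaseEstimator):
    """Estimator wrapper: fit builds the signature, transform estimates fractions.

    Parameters mirror :func:`build_signature_matrix` and
    :func:`estimate_fractions`.  After ``fit``, ``signature_`` holds the
    genes x types signature matrix.
    """

    def __init__(self, top_genes=50, q_threshold=0.3, n_perm=1000,
                 method="svr", nus=(0.25, 0.5, 0.75), random_state=0):
        self.top_genes = top_genes
        self.q_threshold = q_threshold
        self.n_perm = n_perm
        self.method = method
        self.nus = nus
        self.random_state = random_state

    def fit(self, refs: pd.DataFrame, type_map: pd.Series):
        self.signature_ = build_signature_matrix(
            refs, type_map, top_genes=self.top_genes, q_threshold=self.q_threshold
        )
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        return estimate_fractions(
            expr, self.signature_, n_perm=self.n_perm,
            seed=self.random_state, method=self.method, nus=self.nus,
        )

    def fit_transform(self, refs, type_map, expr):
        return self.fit(refs, type_map).transform(expr)
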