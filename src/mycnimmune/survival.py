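"""Survival validation of the immune score.

Kaplan-Meier curves with a k-sample log-rank test across score strata,
multivariate Cox proportional-hazards fits (Efron ties) to test
independence from clinical covariates, and score-panel gene correlations
(immune checkpoints, MHC, TLRs, cytokines).  Overall and event-free
survival share this code path; the caller chooses which clinical columns
supply (time, event).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mycnimmune")

__all__ = ["kaplan_meier_logrank", "cox_multivariate", "panel_correlation"]


def kaplan_meier_logrank(strata, surv_time, surv_event):
    """Product-limit curves per stratum plus the k-sample log-rank test.

    Returns ``(km_tables, test)``: per-stratum DataFrames with columns
    ``time``, ``survival``, ``at_risk``, and a dict with the log-rank
    statistic, degrees of freedom and p-value.  Empty strata are dropped
    with a warning.
    """
    s = pd.Series(np.asarray(strata))
    t = np.asarray(surv_time, dtype=float)
    d = np.asarray(surv_event, dtype=int)
    tables = {}
    kept = []
    for level in pd.unique(s):
        m = (s == level).to_numpy()
        if m.sum() == 0:
            logger.warning("stratum %r has no samples; dropped", level)
            continue
        if d[m].sum() == 0:
            logger.warning("stratum %r has no events", level)
        kept.append(level)
        km = KaplanMeierFitter()
        km.fit(t[m], d[m], label=str(level))
        tab = km.event_table
        tables[level] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(),
                "survival": km.survival_function_.iloc[:, 0].reindex(tab.index).to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
            }
        )
    if len(kept) < 2:
        raise ValueError("need >= 2 non-empty strata for the log-rank test")
    mask = s.isin(kept).to_numpy()
    res = multivariate_logrank_test(t[mask], s[mask].to_numpy(), d[mask])
    test = {
        "statistic": float(res.test_statistic),
        "df": int(res.degrees_of_freedom),
        "p": float(res.p_value),
    }
    return tables, test


def cox_multivariate(covariates: pd.DataFrame, surv_time, surv_event) -> pd.DataFrame:
    """Multivariate Cox PH fit; returns HR, 95% CI and Wald p per covariate."""
    df = covariates.copy()
    df["surv_time"] = np.asarray(surv_time, dtype=float)
    df["surv_event"] = np.asarray(surv_event, dtype=int)
    if df["surv_event"].sum() < 20:
        raise ValueError("need >= 20 events for a multivariate Cox fit")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="surv_time", event_col="surv_event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        cond = np.linalg.cond(np.asarray(covariates, dtype=float))
        raise RuntimeError(
            f"Cox fit failed to converge (design condition number {cond:.1e}): {exc}"
        ) from exc
    summ = cph.summary
    return pd.DataFrame(
        {
            "HR": summ["exp(coef)"],
            "HR_lower95": summ["exp(coef) lower 95%"],
            "HR_upper95": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )


def panel_correlation(score_z, expr: pd.DataFrame, gene_panel) -> pd.DataFrame:
    """Pearson correlation of each panel gene's expression with the score.

    Missing panel genes are reported (logged) and omitted.  Returns one
    row per present gene with r, p, BH q and the correlation direction.
    """
    z = np.asarray(score_z, dtype=float)
    present = [g for g in gene_panel if g in expr.index]
    missing = [g for g in gene_panel if g not in expr.index]
    if missing:
        logger.warning("panel genes missing from the cohort: %s", missing)
    rows = []
    for g in present:
        x = expr.loc[g].to_numpy(dtype=float)
        if x.std() == 0:
            r, p = np.nan, 1.0
        else:
            r, p = stats.pearsonr(x, z)
        rows.append({"gene": g, "r": r, "p": p})
    out = pd.DataFrame(rows, columns=["gene", "r", "p"]).set_index("gene")
    if not out.empty:
        out["q"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
        out["direction"] = np.where(out["r"] >= 0, "positive", "negative")
    return out
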