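"""Cohort-level scoring and outcome association.

Bulk samples are scored for cell-state abundance with single-sample GSEA
(rank-weighted running-sum enrichment, exponent alpha = 0.25, no cross-sample
rescaling by default). Scores feed a continuous Cox proportional-hazards fit,
a median-split Kaplan-Meier / log-rank comparison, a dual-median risk grouping
(low risk = above the median on *both* state scores), and Fisher/chi-squared
association of groups with categorical sample features.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io import ExpressionMatrix


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment for one sample.

    Genes are walked in order of decreasing expression (ties broken by index);
    in-set genes accumulate weight (n - r + 1)^alpha with r the average rank,
    out-set genes accumulate uniformly; ES is the sum of the running
    differences over all positions.
    """
    n = expr.size
    m = int(in_set.sum())
    ranks = stats.rankdata(-expr, method="average")  # 1 = highest expression
    weight = (n - ranks + 1.0) ** alpha
    order = np.argsort(-expr, kind="stable")
    inset_ord = in_set[order]
    w_ord = np.where(inset_ord, weight[order], 0.0)
    p_in = np.cumsum(w_ord) / w_ord.sum()
    p_out = np.cumsum(~inset_ord) / (n - m)
    return float((p_in - p_out).sum())


def ssgsea_score(bulk: ExpressionMatrix, sets: Sequence, alpha: float = 0.25,
                 normalize: bool = False) -> pd.DataFrame:
    """ssGSEA enrichment per sample (rows) and gene set (columns).

    ``normalize=True`` min-max rescales each set's scores across samples (the
    cross-cohort normalization some implementations apply); the default leaves
    raw enrichment sums.
    """
    n = bulk.n_genes
    gene_pos = {g: i for i, g in enumerate(bulk.gene_names)}
    out = pd.DataFrame(index=pd.Index(bulk.cell_ids, name="sample_id"),
                       columns=[s.name for s in sets], dtype=float)
    for s in sets:
        idx = [gene_pos[g] for g in s.genes if g in gene_pos]
        if len(idx) < 2:
            raise ValueError(f"gene set {s.name!r} shares fewer than 2 genes with the matrix")
        if len(idx) == n:
            raise ValueError(f"gene set {s.name!r} covers every gene; enrichment undefined")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        for j, sample in enumerate(bulk.cell_ids):
            out.loc[sample, s.name] = _ssgsea_sample(bulk.values[:, j], mask, alpha)
    if normalize:
        lo, hi = out.min(), out.max()
        span = (hi - lo).replace(0, 1.0)
        out = (out - lo) / span
    return out


# ---------------------------------------------------------------------------
# grouping and survival
# ---------------------------------------------------------------------------

def median_split(scores: pd.Series) -> pd.Series:
    """"high" for scores strictly above the median, "low" otherwise (ties -> low)."""
    if len(scores) < 2:
        raise ValueError("median_split needs >= 2 samples")
    med = scores.median()
    groups = pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    if (groups == "low").all():
        warnings.warn("all scores at or below the median; every sample grouped low",
                      stacklevel=2)
    return groups


def survival_assoc(scores: pd.Series, time: pd.Series, event: pd.Series,
                   second_scores: pd.Series | None = None) -> dict:
    """Cox PH on the continuous score plus median-split KM log-rank.

    With ``second_scores`` the model is score1 + score2 + score1*score2 and the
    reported HR/CI/p belong to the multiplicative interaction term. Returns
    HR, CI95, wald_p, logrank_p, n, n_events and the model formula.
    """
    df = pd.DataFrame({"time": time, "event": event}).astype(float)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events observed; survival model is undefined")
    if n_events < 10:
        warnings.warn(f"only {n_events} events; estimates will be unstable", stacklevel=2)
    if scores.nunique() <= 1:
        raise ValueError("constant covariate")
    if second_scores is None:
        df["score"] = scores.astype(float)
        term, formula = "score", "Surv(time, event) ~ score"
    else:
        df["score1"] = scores.astype(float)
        df["score2"] = second_scores.astype(float)
        df["interaction"] = df["score1"] * df["score2"]
        term = "interaction"
        formula = "Surv(time, event) ~ score1 + score2 + score1:score2"
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_[term]))
    ci = cph.confidence_intervals_.loc[term]
    ci95 = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
    wald_p = float(cph.summary.loc[term, "p"])
    groups = median_split(scores)
    hi, lo = groups == "high", groups == "low"
    lr = logrank_test(df.loc[hi.values, "time"], df.loc[lo.values, "time"],
                      event_observed_A=df.loc[hi.values, "event"],
                      event_observed_B=df.loc[lo.values, "event"])
    return {
        "HR": hr, "CI95": ci95, "wald_p": wald_p, "logrank_p": float(lr.p_value),
        "n": int(len(df)), "n_events": n_events, "formula": formula,
    }


def km_curve_data(time: pd.Series, event: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates per group, for TSV export."""
    out = []
    for g in sorted(groups.unique()):
        sel = (groups == g).values
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=str(g))
        tab = km.event_table
        surv = km.survival_function_
        out.append(pd.DataFrame({
            "group": str(g),
            "time": surv.index.to_numpy(),
            "survival": surv.iloc[:, 0].to_numpy(),
            "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def risk_groups(scores_int: pd.Series, scores_exh: pd.Series) -> tuple[pd.Series, dict]:
    """Dual-median risk grouping.

    Low risk = strictly above the median on both the tumor-intermediate and
    the CD8-exhausted abundance score; everyone else is high risk.
    """
    if not scores_int.index.equals(scores_exh.index):
        scores_exh = scores_exh.loc[scores_int.index]
    med_int, med_exh = scores_int.median(), scores_exh.median()
    low = (scores_int > med_int) & (scores_exh > med_exh)
    groups = pd.Series(np.where(low, "low", "high"), index=scores_int.index)
    return groups, {"median_intermediate": float(med_int), "median_exhausted": float(med_exh)}


def categorical_assoc(groups: pd.Series, labels: pd.Series) -> dict:
    """Fisher exact (2x2, two-sided) or chi-squared (larger tables) association."""
    table = pd.crosstab(groups, labels)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("both variables need >= 2 observed levels")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty category level")
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
        test = "fisher"
    else:
        p = stats.chi2_contingency(table.to_numpy()).pvalue
        test = "chisq"
    return {"test": test, "p": float(p), "table": table}
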