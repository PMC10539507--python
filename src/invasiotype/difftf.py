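"""Differential TF activity between low- and high-invasion groups.

Per-TF activity rows are compared with a pooled-variance two-sample
Student t test, p-values are adjusted by Benjamini-Hochberg step-up, and
significant TFs are split into invasion-promoting (activity elevated in
the high-invasion group) and invasion-suppressing (elevated in the low
group).  A final filter keeps candidates whose own gene is highly
expressed on average, operationalized as a quantile cutoff over the
candidates' own-gene mean expression.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = ["group_ttest", "bh_fdr", "select_tfs", "significance_correlation"]

#: column order of the differential-record table
RECORD_COLUMNS = [
    "feature_id", "mean_low", "mean_high", "t_stat", "p_value", "q_value",
    "direction", "mean_expression", "resolved", "selected",
]


def _split_groups(labels: Mapping[str, str] | pd.Series) -> tuple[list, list]:
    labels = pd.Series(labels)
    bad = set(labels.unique()) - {"low", "high"}
    if bad:
        raise DomainError(f"labels must be 'low'/'high', got {sorted(bad)}")
    low = list(labels.index[labels == "low"])
    high = list(labels.index[labels == "high"])
    return low, high


def _pooled_ttest(a: np.ndarray, b: np.ndarray, welch: bool = False):
    """Two-sample t along the last axis; zero-variance ties give t=0, p=1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=-1, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # 0/0 (all values identical across both groups) -> no evidence: t=0, p=1
    undef = np.isnan(t)
    t = np.where(undef, 0.0, t)
    p = np.where(undef, 1.0, p)
    return t, p


def group_ttest(
    values: Mapping[str, float] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
    welch: bool = False,
) -> tuple[float, float]:
    """Pooled-variance Student t of low- vs high-group values (two-tailed).

    The statistic is mean(low) - mean(high) over its pooled standard error,
    with n1 + n2 - 2 degrees of freedom; set ``welch=True`` for the
    unequal-variance variant.
    """
    values = pd.Series(values, dtype=float)
    low, high = _split_groups(labels)
    low = [s for s in low if s in values.index]
    high = [s for s in high if s in values.index]
    if len(low) < 2 or len(high) < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    t, p = _pooled_ttest(values.loc[low].to_numpy(), values.loc[high].to_numpy(),
                         welch=welch)
    return float(t), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_tfs(
    activity: pd.DataFrame,
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    fdr_threshold: float = 0.05,
    expression_quantile: float = 0.5,
    welch: bool = False,
) -> pd.DataFrame:
    """Rank TFs by differential activity and apply the expression filter.

    Parameters
    ----------
    activity
        TF x sample activity scores (quantile-normalized or raw).
    expr
        Gene x sample expression used to resolve each TF's own gene.
    labels
        sample -> 'low'/'high' invasion group.
    fdr_threshold
        BH q-value cutoff defining candidate TFs.
    expression_quantile
        Candidates whose own-gene mean expression falls below this quantile
        of all resolvable candidates' means are dropped; ``0`` disables the
        filter.  TFs with no matching gene symbol skip the filter and are
        flagged ``resolved=False``.

    Returns
    -------
    DataFrame with one row per TF (columns ``RECORD_COLUMNS``), sorted by
    q-value then TF id.
    """
    labels = pd.Series(labels)
    shared = [s for s in activity.columns if s in labels.index]
    if not shared:
        raise AlignmentError("activity and labels share no sample identifiers")
    sub_labels = labels.loc[shared]
    low, high = _split_groups(sub_labels)
    if len(low) < 2 or len(high) < 2:
        raise InsufficientDataError("each group needs >= 2 samples")

    a_low = activity[low].to_numpy(dtype=float)
    a_high = activity[high].to_numpy(dtype=float)
    t, p = _pooled_ttest(a_low, a_high, welch=welch)
    q = bh_fdr(p)
    mean_low = a_low.mean(axis=1)
    mean_high = a_high.mean(axis=1)

    tf_ids = list(activity.index)
    resolved = np.array([tf in expr.index for tf in tf_ids])
    mean_expr = np.full(len(tf_ids), np.nan)
    if resolved.any():
        expr_cols = [s for s in shared if s in expr.columns]
        if not expr_cols:
            raise AlignmentError("expression and activity share no sample identifiers")
        hit = [tf for tf, ok in zip(tf_ids, resolved) if ok]
        mean_expr[resolved] = expr.loc[hit, expr_cols].mean(axis=1).to_numpy()
    n_unresolved = int((~resolved).sum())
    if n_unresolved:
        logger.info("%d TF(s) had no matching gene symbol; expression filter skipped "
                    "for them", n_unresolved)

    candidate = q < fdr_threshold
    selected = candidate.copy()
    pool = mean_expr[candidate & resolved]
    if expression_quantile > 0 and pool.size:
        cutoff = np.quantile(pool, expression_quantile)
        selected &= ~resolved | (mean_expr >= cutoff)
        logger.info("expression filter: quantile %.2f of candidate means = %.3f",
                    expression_quantile, cutoff)

    records = pd.DataFrame({
        "feature_id": tf_ids,
        "mean_low": mean_low,
        "mean_high": mean_high,
        "t_stat": t,
        "p_value": p,
        "q_value": q,
        "direction": np.where(mean_high > mean_low, "promoting", "suppressing"),
        "mean_expression": mean_expr,
        "resolved": resolved,
        "selected": selected,
    })[RECORD_COLUMNS]
    return records.sort_values(["q_value", "feature_id"], kind="mergesort",
                               ignore_index=True)


def significance_correlation(
    activity_p: Mapping[str, float] | pd.Series,
    expression_p: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation of -log10(p) between activity and expression tests.

    A positive correlation over TFs indicates that factors whose target-set
    activity separates the invasion groups also separate them by their own
    gene's expression, validating the inferred TF-target relationship.
    """
    pa = pd.Series(activity_p, dtype=float)
    pe = pd.Series(expression_p, dtype=float)
    shared = pa.index.intersection(pe.index)
    if len(shared) < 3:
        raise InsufficientDataError("need >= 3 shared TFs")
    pa, pe = pa.loc[shared], pe.loc[shared]
    if (pa <= 0).any() or (pe <= 0).any():
        raise DomainError("p-values must be > 0 for the -log10 transform")
    r, p = stats.pearsonr(-np.log10(pa), -np.log10(pe))
    return float(r), float(p)
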