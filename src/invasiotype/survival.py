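"""Kaplan-Meier estimation, log-rank testing, and score-quantile stratification.

The product-limit estimator and the log-rank statistic are delegated to
lifelines; this module adds the table conventions of the pipeline (TSV
with sample_id / time / event / group columns), input validation, the
Bonferroni adjustment used after multi-group log-rank comparisons, and
stratification of a cohort into the lowest / highest score fractions.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .errors import (
    DomainError,
    InsufficientDataError,
    ParameterError,
    StratificationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "km_estimate",
    "logrank_test",
    "bonferroni_adjust",
    "stratify_by_score",
]


def km_estimate(
    times: Sequence[float],
    events: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored`` and ``survival`` (the estimate
    just after that time).  Subjects censored at an event time are counted
    at risk for that time (events processed first).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InsufficientDataError("need >= 1 subject")
    if np.any(times <= 0):
        raise DomainError("all times must be > 0")
    if events is None:
        events = np.ones_like(times, dtype=int)
    events = np.asarray(events, dtype=int)
    if set(np.unique(events)) - {0, 1}:
        raise DomainError("event indicators must be 0 or 1")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.copy()
    table = table[table.index > 0]
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index)
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "events": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
        "survival": surv.to_numpy(dtype=float),
    }).reset_index(drop=True)
    return out


def logrank_test(table: pd.DataFrame) -> tuple[float, float]:
    """Log-rank chi-square over the groups of a survival table.

    ``table`` needs columns ``time``, ``event`` and ``group``; with g
    groups the statistic has g - 1 degrees of freedom.
    """
    for col in ("time", "event", "group"):
        if col not in table.columns:
            raise ParameterError(f"survival table lacks column {col!r}")
    if np.any(table["time"].to_numpy(dtype=float) <= 0):
        raise DomainError("all times must be > 0")
    groups = [g for g, sub in table.groupby("group") if len(sub)]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 non-empty groups")
    if int(table["event"].sum()) == 0:
        raise InsufficientDataError("log-rank test undefined without events")
    if len(groups) == 2:
        a = table[table["group"] == groups[0]]
        b = table[table["group"] == groups[1]]
        res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                          event_observed_B=b["event"])
    else:
        res = multivariate_logrank_test(table["time"], table["group"], table["event"])
    return float(res.test_statistic), float(res.p_value)


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """min(1, p * m) for each p; ``m`` is the number of comparisons."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ParameterError(f"m={m} smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, p * m)


def stratify_by_score(
    scores: Mapping[str, float] | pd.Series,
    lower_fraction: float = 0.2,
    upper_fraction: float = 0.2,
) -> pd.Series:
    """Label the lowest / highest score fractions ``low`` / ``high``.

    Group sizes are floor(n * fraction) order statistics; samples between
    the cuts are labelled ``excluded``.  Ties at a boundary are broken by
    sample-id order (and logged), so the grouping is deterministic.
    """
    scores = pd.Series(scores, dtype=float)
    n = len(scores)
    if n < 2:
        raise InsufficientDataError("stratification needs >= 2 samples")
    if not (0 < lower_fraction and 0 < upper_fraction
            and lower_fraction + upper_fraction <= 1):
        raise ParameterError("fractions must be > 0 and sum to <= 1")
    k_low = int(np.floor(n * lower_fraction))
    k_high = int(np.floor(n * upper_fraction))
    if k_low == 0 or k_high == 0:
        raise StratificationError(
            f"n={n} with fractions {lower_fraction}/{upper_fraction} "
            "gives an empty group")
    order = scores.reset_index()
    order.columns = ["sample_id", "score"]
    order = order.sort_values(["score", "sample_id"], kind="mergesort")
    ordered_ids = order["sample_id"].tolist()
    ordered_scores = order["score"].to_numpy()
    for cut, name in ((k_low, "low"), (n - k_high, "high")):
        if 0 < cut < n and ordered_scores[cut - 1] == ordered_scores[cut]:
            logger.info("tie at the %s-group boundary broken by sample-id order", name)
    labels = pd.Series("excluded", index=scores.index, name="label")
    labels.loc[ordered_ids[:k_low]] = "low"
    labels.loc[ordered_ids[n - k_high:]] = "high"
    return labels
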