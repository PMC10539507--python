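"""Invasion phenotyping of tumorspheres and matched tumors.

Two dimensionless indices quantify invasiveness:

* 3D-assay index: relative growth of the spheroid-occupied area over 72 h
  in a collagen matrix, ``(area_72h - area_0h) / area_0h``;
* MRI index: relative excess of the T2-FLAIR area over the T1
  contrast-enhanced area, ``(FLAIR - CE) / CE``, a radiological surrogate
  for infiltration beyond the enhancing tumor core.

Samples are dichotomized into low/high-invasion groups either by a
user-supplied threshold or by the optimal two-group split of the sorted
indices (minimum total within-group sum of squares).
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AmbiguityError, DomainError, InsufficientDataError, ParameterError

__all__ = [
    "invasion_index",
    "mri_invasion_index",
    "add_indices",
    "classify_invasion",
    "spearman_correlation",
]


def invasion_index(area_0h: float, area_72h: float) -> float:
    """3D-invasion index (72 h - 0 h) / 0 h from spheroid-occupied areas."""
    if area_0h <= 0:
        raise DomainError(f"area_0h must be > 0, got {area_0h}")
    if area_72h < 0:
        raise DomainError(f"area_72h must be >= 0, got {area_72h}")
    return (area_72h - area_0h) / area_0h


def mri_invasion_index(flair_area: float, ce_area: float) -> float:
    """MRI invasion index (T2 FLAIR - T1 CE) / T1 CE from segmented areas."""
    if ce_area <= 0:
        raise DomainError(f"ce_area must be > 0, got {ce_area}")
    return (flair_area - ce_area) / ce_area


def add_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Append ts_index / mri_index columns where the source areas are present."""
    out = table.copy()
    if {"area_0h", "area_72h"}.issubset(out.columns):
        out["ts_index"] = [
            invasion_index(a0, a72) for a0, a72 in zip(out["area_0h"], out["area_72h"])
        ]
    if {"flair_area", "ce_area"}.issubset(out.columns):
        out["mri_index"] = [
            mri_invasion_index(f, c) for f, c in zip(out["flair_area"], out["ce_area"])
        ]
    return out


def classify_invasion(
    indices: Mapping[str, float] | pd.Series,
    method: str = "two_partition",
    threshold: float | None = None,
) -> pd.Series:
    """Label every sample ``low`` or ``high`` from its invasion index.

    ``two_partition`` places the cut between consecutive sorted indices so
    that the total within-group sum of squared deviations is minimal
    (exhaustive over the n-1 cut points); ``threshold`` labels samples
    above the given cutoff ``high``.
    """
    idx = pd.Series(indices, dtype=float)
    if len(idx) < 2:
        raise InsufficientDataError("classification needs >= 2 samples")
    if method == "threshold":
        if threshold is None:
            raise ParameterError("method='threshold' requires a threshold")
        labels = pd.Series(np.where(idx > threshold, "high", "low"), index=idx.index)
    elif method == "two_partition":
        if threshold is not None:
            raise ParameterError("threshold is only valid with method='threshold'")
        if idx.nunique() == 1:
            raise AmbiguityError("all indices identical; two-group split is ambiguous")
        order = idx.sort_values(kind="mergesort").index
        x = idx.loc[order].to_numpy()
        n = len(x)
        best_cut, best_ss = None, math.inf
        for cut in range(1, n):
            lo, hi = x[:cut], x[cut:]
            ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if ss < best_ss - 1e-12:
                best_ss, best_cut = ss, cut
        labels = pd.Series("high", index=idx.index)
        labels.loc[order[:best_cut]] = "low"
    else:
        raise ParameterError(f"unknown classification method {method!r}")
    if (labels == "low").all() or (labels == "high").all():
        raise AmbiguityError("classification produced an empty group")
    labels.name = "label"
    return labels


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p-value at small n.

    rho is the Pearson correlation of mid-ranks (average-rank ties).  For
    n <= 7 the two-sided p-value is computed from the full permutation
    distribution of the rank pairing; for larger n the usual Student-t
    approximation with n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Spearman correlation needs n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DomainError("zero rank variance; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)
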