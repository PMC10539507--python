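"""Single-sample gene-set enrichment (ssGSEA) and score post-processing.

The enrichment score of a gene set S in one sample is the integrated
difference between two empirical distribution functions walked down the
sample's expression-ranked gene list: a weighted hit ECDF over the members
of S (weights are the rank magnitudes raised to the exponent ``tau``) and
an unweighted miss ECDF over the remaining genes,

    ES = sum_i [ P_hit(i) - P_miss(i) ],    i = 1..N positions.

A set enriched among highly expressed genes scores positive, one enriched
among lowly expressed genes scores negative.  Transcription-factor (TF)
activity is summarized by scoring every target set of a TF and averaging
the per-set scores; score matrices are then quantile-normalized so every
sample shares one score distribution.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSetError,
    EmptyResultError,
    MappingError,
    MissingSetError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegulonCollection",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "enrichment_matrix",
    "collapse_by_tf",
    "quantile_normalize",
    "signature_score",
]


@dataclass
class RegulonCollection:
    """Named TF-target gene sets with a set-name -> TF attribution.

    A TF may own several partially overlapping sets (as in MSigDB c3.tft,
    where one factor appears under several binding-motif entries).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    tf_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ParameterError(f"gene set {name!r} is empty")
            if name not in self.tf_of:
                raise MappingError(f"gene set {name!r} has no TF attribution")

    @property
    def tfs(self) -> list[str]:
        seen: dict[str, None] = {}
        for name in self.sets:
            seen.setdefault(self.tf_of[name], None)
        return list(seen)

    def sets_of(self, tf: str) -> list[str]:
        return [name for name in self.sets if self.tf_of[name] == tf]


def read_gmt(path: str | os.PathLike) -> RegulonCollection:
    """Read a GMT file: per line ``set_name<TAB>tf_id<TAB>gene1<TAB>gene2...``.

    The description field carries the owning TF identifier.
    """
    sets: dict[str, list[str]] = {}
    tf_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParameterError(f"malformed GMT line: {line[:80]!r}")
            name, tf = fields[0], fields[1]
            sets[name] = [g for g in fields[2:] if g]
            tf_of[name] = tf
    return RegulonCollection(sets=sets, tf_of=tf_of)


def write_gmt(regulons: RegulonCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in regulons.sets.items():
            fh.write("\t".join([name, regulons.tf_of[name], *genes]) + "\n")


def _rank_magnitudes(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Rank magnitude per gene: N for the highest value down to 1 for the lowest.

    Ties are broken deterministically by gene identifier (ascending), so the
    score is reproducible across platforms and row orderings.
    """
    order = np.lexsort((gene_ids, -values))
    r = np.empty(len(values))
    r[order] = np.arange(len(values), 0, -1)
    return r


def _es_from_magnitudes(rh: np.ndarray, n: int, tau: float) -> float:
    """Closed-form evaluation of the integrated ECDF difference.

    A hit at position p contributes to the running hit ECDF at positions
    p..N, i.e. exactly its rank magnitude r = N - p + 1 times; summing the
    miss ECDF likewise reduces to a difference of rank-magnitude totals.
    """
    s = len(rh)
    w = rh**tau
    hit_integral = float((w * rh).sum() / w.sum())
    total = n * (n + 1) / 2.0
    miss_integral = float((total - rh.sum()) / (n - s))
    return hit_integral - miss_integral


def ssgsea_score(
    sample_values: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    tau: float = 0.25,
) -> float:
    """Enrichment score of ``gene_set`` in one sample.

    Parameters
    ----------
    sample_values
        Gene -> expression value for one sample (log scale).
    gene_set
        Gene identifiers of the set; members absent from the universe are
        ignored (intersection semantics).
    tau
        Weight exponent on the rank magnitudes of hit genes; ``tau=0``
        weighs all hits equally and makes the score purely rank-based.
    """
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau}")
    values = pd.Series(sample_values, dtype=float)
    ids = values.index.to_numpy(dtype=str)
    n = len(values)
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ids), dtype=bool, count=n)
    s = int(mask.sum())
    if s == 0:
        raise MissingSetError("gene set has no member in the expression universe")
    if s == n:
        raise DegenerateSetError("gene set covers the entire gene universe")
    r = _rank_magnitudes(values.to_numpy(dtype=float), ids)
    return _es_from_magnitudes(r[mask], n, tau)


def enrichment_matrix(
    expr: pd.DataFrame,
    regulons: RegulonCollection,
    tau: float = 0.25,
) -> pd.DataFrame:
    """Score every regulon in every sample: rows = set names, columns = samples.

    Sets with no gene in the expression universe are dropped with a logged
    warning; if every set is dropped an :class:`EmptyResultError` is raised.
    """
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau}")
    n, n_samples = expr.shape
    ids = expr.index.to_numpy(dtype=str)
    row_of = {g: i for i, g in enumerate(ids)}
    values = expr.to_numpy(dtype=float)

    # one descending rank pass per sample, reused by every set
    magnitudes = np.empty_like(values)
    for j in range(n_samples):
        magnitudes[:, j] = _rank_magnitudes(values[:, j], ids)

    total = n * (n + 1) / 2.0
    rows: dict[str, np.ndarray] = {}
    dropped = []
    for name, genes in regulons.sets.items():
        idx = np.array(sorted({row_of[g] for g in genes if g in row_of}), dtype=int)
        if idx.size == 0:
            dropped.append(name)
            continue
        if idx.size == n:
            raise DegenerateSetError(f"gene set {name!r} covers the entire gene universe")
        rh = magnitudes[idx, :]
        w = rh**tau
        es = (w * rh).sum(axis=0) / w.sum(axis=0) - (total - rh.sum(axis=0)) / (n - idx.size)
        rows[name] = es
    if dropped:
        logger.warning("dropped %d gene set(s) with no gene in the universe: %s",
                       len(dropped), ", ".join(dropped[:10]))
    if not rows:
        raise EmptyResultError("every gene set was dropped; no scores to report")
    return pd.DataFrame(rows, index=expr.columns).T


def collapse_by_tf(set_scores: pd.DataFrame, tf_of: Mapping[str, str]) -> pd.DataFrame:
    """Average same-TF set scores into a single TF x sample activity matrix."""
    unmapped = [name for name in set_scores.index if name not in tf_of]
    if unmapped:
        raise MappingError(f"set name(s) without TF attribution: {unmapped[:5]}")
    tf_index = pd.Index([tf_of[name] for name in set_scores.index], name="tf")
    return set_scores.groupby(tf_index, sort=True).mean()


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one value distribution.

    The value at within-column rank k is replaced by the mean of the k-th
    order statistics across columns; a run of tied values within a column
    receives the mean of the reference values its ranks span.
    """
    if matrix.shape[1] < 2:
        raise ParameterError("quantile normalization needs >= 2 columns")
    vals = matrix.to_numpy(dtype=float)
    n, m = vals.shape
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(m):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # cumulative mean over each tied run of the reference vector
        boundaries = np.flatnonzero(np.diff(sorted_col)) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n]))
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        for a, b in zip(starts, stops):
            out[order[a:b], j] = (csum[b] - csum[a]) / (b - a)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def signature_score(
    expr: pd.DataFrame,
    signature: Sequence[str],
    tau: float = 0.25,
) -> pd.Series:
    """Per-sample enrichment of one signature set (e.g. stromal/immune genes).

    This is the single-set view of :func:`enrichment_matrix`, exposed for
    ESTIMATE-style scoring of bulk cohorts.
    """
    fake = RegulonCollection(sets={"signature": list(signature)},
                             tf_of={"signature": "signature"})
    try:
        scores = enrichment_matrix(expr, fake, tau=tau)
    except EmptyResultError:
        raise MissingSetError("signature has no member in the expression universe") from None
    return scores.loc["signature"]
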