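"""Callset performance metrics and pooled pairwise distance matrices.

Four metrics are supported: event-based precision and recall, their F1
combination, and the base-pair Jaccard similarity.  Each metric ``q`` yields
a distance ``delta = 1 - q``; distances over many observations are pooled
into a weighted-average matrix that also carries a distinguished truth row
when truth callsets are available.
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np

from svfuse.core import TRUTH_ID, BinScheme, Callset, Observation, PartitionKey, partition
from svfuse.errors import DataError
from svfuse.intervals import coverage, intersect, merge, overlap_bp

log = logging.getLogger(__name__)


class MetricKind(str, Enum):
    prec = "prec"
    rec = "rec"
    F1 = "F1"
    J = "J"


def _merged_by_type(cs: Callset) -> dict[str, list[tuple[int, int]]]:
    by_type: dict[str, list] = {}
    for c in cs:
        by_type.setdefault(c.sv_type, []).append(c.interval)
    return {t: merge(v) for t, v in by_type.items()}


def bp_intersection(a: Callset, b: Callset, type_match: bool = False) -> int:
    """bp covered by at least one call in *a* and at least one call in *b*.

    Coverage is multiplicity-free on each side.  With ``type_match`` the
    intersection is computed per sv_type and summed, so a DEL never
    intersects a DUP.
    """
    if type_match:
        ma, mb = _merged_by_type(a), _merged_by_type(b)
        return sum(
            coverage(intersect(ma[t], mb[t])) for t in ma.keys() & mb.keys()
        )
    return coverage(intersect(merge(a.intervals()), merge(b.intervals())))


def jaccard(a: Callset, b: Callset) -> float:
    """Base-pair Jaccard similarity |a n b| / |a u b|; 1.0 when both empty."""
    ma, mb = merge(a.intervals()), merge(b.intervals())
    union = coverage(merge(list(ma) + list(mb)))
    if union == 0:
        log.debug("jaccard: both callsets empty, returning 1.0 by convention")
        return 1.0
    return coverage(intersect(ma, mb)) / union


def _overlap_hits(queries: Callset, targets: Callset, reciprocal_overlap: float) -> int:
    """Number of query calls overlapped by >=1 target call at the criterion."""
    tgt = sorted(targets.intervals())
    hits = 0
    j0 = 0
    for q in queries:
        # advance past targets entirely left of the query
        while j0 < len(tgt) and tgt[j0][1] < q.s_start:
            j0 += 1
        j = j0
        while j < len(tgt) and tgt[j][0] <= q.s_end:
            ov = overlap_bp(q.s_start, q.s_end, tgt[j][0], tgt[j][1])
            tlen = tgt[j][1] - tgt[j][0] + 1
            if ov > 0 and (
                reciprocal_overlap <= 0.0
                or (ov >= reciprocal_overlap * q.size and ov >= reciprocal_overlap * tlen)
            ):
                hits += 1
                break
            j += 1
    return hits


def precision(c: Callset, truth: Callset, reciprocal_overlap: float = 0.0) -> float:
    """Fraction of calls in *c* overlapped by at least one truth call.

    Empty *c* scores 1.0 (no false positives) by convention.
    """
    if len(c) == 0:
        log.debug("precision: empty callset, returning 1.0 by convention")
        return 1.0
    return _overlap_hits(c, truth, reciprocal_overlap) / len(c)


def recall(c: Callset, truth: Callset, reciprocal_overlap: float = 0.0) -> float:
    """Fraction of truth calls recovered by *c*; empty truth scores 1.0."""
    if len(truth) == 0:
        log.debug("recall: empty truth, returning 1.0 by convention")
        return 1.0
    return _overlap_hits(truth, c, reciprocal_overlap) / len(truth)


def f1(p: float, r: float) -> float:
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def distance(
    a: Callset,
    b: Callset,
    metric: MetricKind = MetricKind.J,
    reciprocal_overlap: float = 0.0,
) -> float:
    """``1 - q(a, b)`` for the chosen metric ``q``."""
    metric = MetricKind(metric)
    if metric is MetricKind.J:
        q = jaccard(a, b)
    elif metric is MetricKind.prec:
        q = precision(a, b, reciprocal_overlap)
    elif metric is MetricKind.rec:
        q = recall(a, b, reciprocal_overlap)
    else:
        q = f1(precision(a, b, reciprocal_overlap), recall(a, b, reciprocal_overlap))
    return 1.0 - q


class DistanceMatrix:
    """Pooled weighted pairwise distances among callers (and optionally truth).

    ``ids`` orders the rows/columns; the truth callset, when present, is the
    row with id :data:`~svfuse.core.TRUTH_ID`.
    """

    def __init__(self, ids, matrix, metric: MetricKind, weights=None):
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=float)
        self.metric = MetricKind(metric)
        self.weights = None if weights is None else list(weights)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise DataError("distance matrix shape does not match id index")
        self._pos = {cid: k for k, cid in enumerate(self.ids)}

    @property
    def has_truth(self) -> bool:
        return TRUTH_ID in self._pos

    def get(self, i: int, j: int) -> float:
        return float(self.matrix[self._pos[i], self._pos[j]])

    def to_truth(self, i: int) -> float:
        if not self.has_truth:
            raise DataError("distance matrix has no truth row")
        return self.get(i, TRUTH_ID)

    def restrict(self, ids) -> "DistanceMatrix":
        """Sub-matrix over a subset of ids, preserving their given order."""
        idx = [self._pos[i] for i in ids]
        return DistanceMatrix(ids, self.matrix[np.ix_(idx, idx)], self.metric)

    def to_dict(self) -> dict:
        return {
            "ids": self.ids,
            "matrix": self.matrix.tolist(),
            "metric": self.metric.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceMatrix":
        return cls(d["ids"], d["matrix"], MetricKind(d["metric"]))


def _restrict(cs: Callset, key: PartitionKey | None, bins: BinScheme | None) -> Callset:
    if key is None:
        return cs
    if bins is None:
        raise DataError("a PartitionKey restriction requires a BinScheme")
    return partition(cs, bins).get(key, cs.with_calls([]))


def pooled_distance_matrix(
    observations: list[Observation],
    weights=None,
    metric: MetricKind = MetricKind.J,
    include_truth: bool = False,
    key: PartitionKey | None = None,
    bins: BinScheme | None = None,
    reciprocal_overlap: float = 0.0,
) -> DistanceMatrix:
    """Weight-averaged pairwise distances over a list of observations.

    Entry (i, j) is ``sum_y w_y * delta(c_i^y, c_j^y) / sum_y w_y``.  With a
    ``key``/``bins`` restriction each callset is first reduced to that
    partition.  For the asymmetric metrics (prec, rec) the two directions are
    averaged so the matrix stays symmetric.
    """
    if not observations:
        raise DataError("pooled_distance_matrix requires at least one observation")
    if weights is None:
        weights = [1.0] * len(observations)
    if len(weights) != len(observations) or any(w <= 0 for w in weights):
        raise DataError("weights must be positive, one per observation")
    caller_ids = observations[0].caller_ids
    for obs in observations[1:]:
        if obs.caller_ids != caller_ids:
            raise DataError("observations have mixed caller sets")
    if include_truth and any(obs.truth is None for obs in observations):
        raise DataError("include_truth requires a truth callset in every observation")

    ids = list(caller_ids) + ([TRUTH_ID] if include_truth else [])
    n = len(ids)
    acc = np.zeros((n, n))
    wsum = float(sum(weights))
    metric = MetricKind(metric)
    for obs, w in zip(observations, weights):
        sets = {cid: _restrict(obs.callsets[cid], key, bins) for cid in caller_ids}
        if include_truth:
            sets[TRUTH_ID] = _restrict(obs.truth, key, bins)
        for a in range(n):
            for b in range(a + 1, n):
                d_ab = distance(sets[ids[a]], sets[ids[b]], metric, reciprocal_overlap)
                if metric in (MetricKind.prec, MetricKind.rec):
                    d_ba = distance(sets[ids[b]], sets[ids[a]], metric, reciprocal_overlap)
                    d_ab = 0.5 * (d_ab + d_ba)
                acc[a, b] += w * d_ab
                acc[b, a] += w * d_ab
    return DistanceMatrix(ids, acc / wsum, metric, weights)
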