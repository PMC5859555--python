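"""Fusion-model training: group expectations over the caller powerset,
segment projection, cutoff fitting and breakpoint-spread estimation.

The expectation of a caller subset G multiplies, over its members i, the
member's accuracy term ``1 - D(c_i, c_t)`` by its dissimilarity term
``max_{j in G\\{i}} D(c_j, c_i)``, so a subset containing two near-identical
callers collapses toward zero while accurate, complementary subsets score
high.  A per-partition cutoff over these expectations is then fitted by
exhaustive search against the truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from svfuse.core import (
    TRUTH_ID,
    BinScheme,
    Call,
    Callset,
    Observation,
    PartitionKey,
    partition,
)
from svfuse.errors import DataError, ModelVersionError
from svfuse.intervals import overlap_bp
from svfuse.similarity import DistanceMatrix, MetricKind, distance, pooled_distance_matrix

log = logging.getLogger(__name__)

MODEL_SCHEMA = "svfuse-model-1"

#: cutoff marker for partitions with no training data: passes nothing
EMPTY_ALPHA = 2.0

#: default ceiling on caller count for exhaustive powerset enumeration
MAX_CALLERS = 12


@dataclass(frozen=True)
class GroupExpectation:
    """Per-partition map from nonempty caller subsets to expectation values."""

    key: PartitionKey | None
    table: dict[frozenset, float]

    def value(self, group: frozenset) -> float:
        try:
            return self.table[frozenset(group)]
        except KeyError:
            raise DataError(f"caller subset {sorted(group)} missing from expectation table") from None

    def candidates(self) -> list[float]:
        """Sorted unique expectation values plus 0 (the cutoff search grid)."""
        return sorted(set(self.table.values()) | {0.0})


@dataclass
class Segment:
    """Maximal interval over which the supporting caller set is constant."""

    start: int
    end: int
    callers: frozenset
    expectation: float
    sv_type: str
    # per caller: (left, right) breakpoints of the contributing call(s)
    breakpoints: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BreakpointSpread:
    """Per-caller sample SDs of the left/right breakpoint differentials."""

    sigma_l: dict[int, float]
    sigma_r: dict[int, float]
    n_l: dict[int, int]
    n_r: dict[int, int]

    def eligible(self, caller_id: int) -> bool:
        """True when the caller has enough differential samples to weight."""
        return self.n_l.get(caller_id, 0) >= 2 and self.n_r.get(caller_id, 0) >= 2


@dataclass
class PartitionModel:
    key: PartitionKey
    expectations: GroupExpectation
    alpha: float
    fitted_distance: float
    empty: bool = False


@dataclass
class FusionModel:
    """Everything needed to score and filter a new sample."""

    caller_ids: list[int]
    bins: BinScheme
    partitions: dict[PartitionKey, PartitionModel]
    spreads: BreakpointSpread
    caller_distance: DistanceMatrix
    metric: MetricKind
    metadata: dict = field(default_factory=dict)

    def partition_model(self, key: PartitionKey) -> PartitionModel | None:
        return self.partitions.get(key)


def _subset_key(group: frozenset) -> str:
    return ",".join(str(i) for i in sorted(group))


def _parse_subset(key: str) -> frozenset:
    return frozenset(int(x) for x in key.split(","))


def group_expectation(group, dmat: DistanceMatrix) -> float:
    """Expectation of one caller subset from a truth-bearing distance matrix.

    For singletons the dissimilarity max runs over an empty set and is taken
    as 1, so E({i}) reduces to caller i's accuracy ``1 - D(c_i, c_t)``.
    """
    group = frozenset(group)
    if not group:
        raise DataError("group expectation of the empty set is undefined")
    if not dmat.has_truth:
        raise DataError("distance matrix lacks a truth row")
    value = 1.0
    for i in group:
        accuracy = 1.0 - dmat.to_truth(i)
        others = group - {i}
        dissim = max(dmat.get(j, i) for j in others) if others else 1.0
        value *= accuracy * dissim
    return min(1.0, max(0.0, value))


def all_group_expectations(
    dmat: DistanceMatrix,
    key: PartitionKey | None = None,
    max_callers: int = MAX_CALLERS,
) -> GroupExpectation:
    """Expectations for every nonempty subset of the matrix's callers."""
    caller_ids = [i for i in dmat.ids if i != TRUTH_ID]
    n = len(caller_ids)
    if n > max_callers:
        raise DataError(
            f"{n} callers exceed the powerset ceiling of {max_callers}; "
            "restrict the caller set or raise the ceiling"
        )
    table = {}
    for r in range(1, n + 1):
        for combo in combinations(caller_ids, r):
            g = frozenset(combo)
            table[g] = group_expectation(g, dmat)
    return GroupExpectation(key, table)


def _check_same_callers(prior_obs, new_obs) -> None:
    idx = prior_obs[0].caller_ids
    for obs in list(prior_obs) + list(new_obs):
        if obs.caller_ids != idx:
            raise DataError("caller index mismatch between prior and new observations")


def update_expectation_with_truth(
    prior_obs: list[Observation],
    prior_weights,
    new_obs: list[Observation],
    new_weights,
    metric: MetricKind = MetricKind.J,
    key: PartitionKey | None = None,
    bins: BinScheme | None = None,
) -> GroupExpectation:
    """Re-estimate expectations after pooling validated new observations.

    The distance matrix (truth included) is recomputed over the prior and new
    observations together, then the expectation form is re-evaluated on it.
    """
    _check_same_callers(prior_obs, new_obs)
    if any(obs.truth is None for obs in new_obs):
        raise DataError("update with truth requires truth callsets in new observations")
    dmat = pooled_distance_matrix(
        list(prior_obs) + list(new_obs),
        list(prior_weights) + list(new_weights),
        metric,
        include_truth=True,
        key=key,
        bins=bins,
    )
    return all_group_expectations(dmat, key)


def update_expectation_without_truth(
    prior_obs: list[Observation],
    prior_weights,
    new_obs: list[Observation],
    new_weights,
    metric: MetricKind = MetricKind.J,
    key: PartitionKey | None = None,
    bins: BinScheme | None = None,
) -> GroupExpectation:
    """Mix truthless new observations into the caller-caller distances only.

    Truth-involving distances stay pooled over the prior observations; the
    caller-caller dissimilarity pool extends over prior plus new, so callers
    that converge on the new data are discounted without any new truth.
    """
    _check_same_callers(prior_obs, new_obs)
    truth_mat = pooled_distance_matrix(
        prior_obs, prior_weights, metric, include_truth=True, key=key, bins=bins
    )
    mixed_mat = pooled_distance_matrix(
        list(prior_obs) + list(new_obs),
        list(prior_weights) + list(new_weights),
        metric,
        include_truth=False,
        key=key,
        bins=bins,
    )
    caller_ids = [i for i in truth_mat.ids if i != TRUTH_ID]
    table = {}
    for r in range(1, len(caller_ids) + 1):
        for combo in combinations(caller_ids, r):
            g = frozenset(combo)
            value = 1.0
            for i in g:
                accuracy = 1.0 - truth_mat.to_truth(i)
                others = g - {i}
                dissim = max(mixed_mat.get(j, i) for j in others) if others else 1.0
                value *= accuracy * dissim
            table[g] = min(1.0, max(0.0, value))
    return GroupExpectation(key, table)


def project(
    callsets: dict[int, Callset],
    expectations: GroupExpectation,
) -> list[Segment]:
    """Decompose the union of calls into maximal constant-support segments.

    Every segment carries its supporting caller set, the looked-up
    expectation for that set, and the original per-caller breakpoints needed
    later for smoothing.
    """
    sv_types = {c.sv_type for cs in callsets.values() for c in cs}
    if len(sv_types) > 1:
        raise DataError(f"projection input mixes sv_types {sorted(sv_types)}")
    sv_type = sv_types.pop() if sv_types else ""

    events = []  # (position, kind, caller_id, call); kind 0=open, 1=close
    for cid, cs in callsets.items():
        for c in cs:
            events.append((c.s_start, 0, cid, c))
            events.append((c.s_end + 1, 1, cid, c))
    if not events:
        return []
    events.sort(key=lambda e: (e[0], e[1]))

    segments: list[Segment] = []
    active: dict[int, list[Call]] = {}
    prev_pos = None
    k = 0
    while k < len(events):
        pos = events[k][0]
        if active and prev_pos is not None and pos > prev_pos:
            callers = frozenset(active)
            bps = {
                cid: (min(c.s_start for c in calls), max(c.s_end for c in calls))
                for cid, calls in active.items()
            }
            seg = Segment(
                prev_pos, pos - 1, callers, expectations.value(callers), sv_type, bps
            )
            last = segments[-1] if segments else None
            if last and last.callers == callers and last.end + 1 == seg.start:
                last.end = seg.end
                for cid, (l, r) in bps.items():
                    pl, pr = last.breakpoints[cid]
                    last.breakpoints[cid] = (min(pl, l), max(pr, r))
            else:
                segments.append(seg)
        while k < len(events) and events[k][0] == pos:
            _, kind, cid, call = events[k]
            if kind == 0:
                active.setdefault(cid, []).append(call)
            else:
                active[cid].remove(call)
                if not active[cid]:
                    del active[cid]
            k += 1
        prev_pos = pos
    return segments


def fuse_segments(segments: list[Segment]) -> list[Segment]:
    """Join adjacent or overlapping segments into proposal spans.

    The joined span keeps the union of supporting callers, a length-weighted
    mean expectation, and merged per-caller breakpoints.
    """
    fused: list[Segment] = []
    for seg in sorted(segments, key=lambda s: (s.start, s.end)):
        if fused and seg.start <= fused[-1].end + 1:
            cur = fused[-1]
            w_cur, w_new = cur.length, seg.length
            cur.expectation = (
                cur.expectation * w_cur + seg.expectation * w_new
            ) / (w_cur + w_new)
            cur.end = max(cur.end, seg.end)
            cur.callers = cur.callers | seg.callers
            for cid, (l, r) in seg.breakpoints.items():
                if cid in cur.breakpoints:
                    pl, pr = cur.breakpoints[cid]
                    cur.breakpoints[cid] = (min(pl, l), max(pr, r))
                else:
                    cur.breakpoints[cid] = (l, r)
        else:
            fused.append(
                Segment(
                    seg.start,
                    seg.end,
                    seg.callers,
                    seg.expectation,
                    seg.sv_type,
                    dict(seg.breakpoints),
                )
            )
    return fused


def _proposal_callset(
    segments: list[Segment], cutoff: float, sample_id: str, sv_type: str
) -> Callset:
    survivors = [s for s in segments if s.expectation >= cutoff]
    fused = fuse_segments(survivors)
    calls = [
        Call(s.start, s.end, sv_type or "DEL", caller_id=TRUTH_ID, sample_id=sample_id)
        for s in fused
    ]
    return Callset(TRUTH_ID, sample_id, calls)


def _pooled_proposal_distance(
    cutoff: float,
    per_obs_segments,
    truths,
    weights,
    metric: MetricKind,
    sv_type: str,
) -> float:
    num = 0.0
    for (segs, truth, w) in zip(per_obs_segments, truths, weights):
        proposal = _proposal_callset(segs, cutoff, truth.sample_id, sv_type)
        num += w * distance(proposal, truth, metric)
    return num / sum(weights)


def fit_cutoff(
    observations: list[Observation],
    expectations: GroupExpectation,
    key: PartitionKey,
    bins: BinScheme,
    weights=None,
    metric: MetricKind = MetricKind.J,
    search: str = "exhaustive",
) -> tuple[float, float]:
    """Fit the expectation cutoff that minimises pooled distance to truth.

    Candidates are the partition's unique expectation values plus 0; for each
    candidate, per-observation proposal callsets are built by dropping
    segments below it and fusing the survivors, and distances to truth are
    pooled by weight.  Ties break toward the larger cutoff.  ``search`` may
    be ``"exhaustive"`` (the oracle) or ``"em"`` (coarse-grid iterative
    refinement for large candidate lists).
    """
    if any(obs.truth is None for obs in observations):
        raise DataError("fit_cutoff requires truth callsets")
    if weights is None:
        weights = [1.0] * len(observations)

    per_obs_segments = []
    truths = []
    for obs in observations:
        parts = {
            cid: partition(cs, bins).get(key, cs.with_calls([]))
            for cid, cs in obs.callsets.items()
        }
        per_obs_segments.append(project(parts, expectations))
        truths.append(partition(obs.truth, bins).get(key, obs.truth.with_calls([])))

    candidates = expectations.candidates()
    if not candidates:
        log.warning("fit_cutoff: no candidate expectations for %s; keeping everything", key)
        return 0.0, _pooled_proposal_distance(
            0.0, per_obs_segments, truths, weights, metric, key.sv_type
        )

    def objective(p: float) -> float:
        return _pooled_proposal_distance(
            p, per_obs_segments, truths, weights, metric, key.sv_type
        )

    if search == "exhaustive":
        scan = list(range(len(candidates)))
    elif search == "em":
        scan = _refinement_indices(candidates, objective)
    else:
        raise DataError(f"unknown search mode {search!r}")

    best_alpha, best_dist = None, None
    for idx in scan:
        p = candidates[idx]
        d = objective(p)
        if best_dist is None or d < best_dist or (d == best_dist and p > best_alpha):
            best_alpha, best_dist = p, d
    return best_alpha, best_dist


def _refinement_indices(candidates, objective, coarse: int = 33) -> list[int]:
    """Coarse grid plus local neighbourhood refinement over candidate indices.

    On candidate lists no longer than the coarse grid this degenerates to the
    full scan, so it agrees with exhaustive search there by construction.
    """
    n = len(candidates)
    if n <= coarse:
        return list(range(n))
    grid = sorted({round(i * (n - 1) / (coarse - 1)) for i in range(coarse)})
    scored = [(objective(candidates[i]), i) for i in grid]
    scored.sort()
    seen = set(grid)
    for _, center in scored[:3]:
        for d in range(-4, 5):
            i = center + d
            if 0 <= i < n:
                seen.add(i)
    return sorted(seen)


def _match_truth(call: Call, truth: Callset) -> Call | None:
    """Truth call with the largest bp overlap (ties to the leftmost)."""
    best, best_ov = None, 0
    for t in truth:
        if t.s_start > call.s_end:
            break
        ov = overlap_bp(call.s_start, call.s_end, t.s_start, t.s_end)
        if ov > best_ov:
            best, best_ov = t, ov
    return best


def estimate_breakpoint_spreads(observations: list[Observation]) -> BreakpointSpread:
    """Sample SDs of per-caller breakpoint offsets against matched truth.

    For every call overlapping a truth call, the differential is caller
    breakpoint minus the breakpoint of the truth call with the largest bp
    overlap.  Callers with fewer than two samples get sigma 0 and are flagged
    ineligible for smoothing.
    """
    diffs_l: dict[int, list[int]] = {}
    diffs_r: dict[int, list[int]] = {}
    for obs in observations:
        if obs.truth is None:
            raise DataError("breakpoint spread estimation requires truth callsets")
        for cid, cs in obs.callsets.items():
            dl = diffs_l.setdefault(cid, [])
            dr = diffs_r.setdefault(cid, [])
            for c in cs:
                t = _match_truth(c, obs.truth)
                if t is None:
                    continue
                dl.append(c.s_start - t.s_start)
                dr.append(c.s_end - t.s_end)
    sigma_l, sigma_r, n_l, n_r = {}, {}, {}, {}
    for cid in diffs_l:
        zl, zr = diffs_l[cid], diffs_r[cid]
        n_l[cid], n_r[cid] = len(zl), len(zr)
        sigma_l[cid] = float(np.std(zl, ddof=1)) if len(zl) >= 2 else 0.0
        sigma_r[cid] = float(np.std(zr, ddof=1)) if len(zr) >= 2 else 0.0
        if len(zl) < 2:
            log.info("caller %d has %d truth overlap(s); excluded from smoothing", cid, len(zl))
    return BreakpointSpread(sigma_l, sigma_r, n_l, n_r)


def train(
    observations: list[Observation],
    weights=None,
    bins: BinScheme | None = None,
    metric: MetricKind = MetricKind.J,
    search: str = "exhaustive",
    metadata: dict | None = None,
) -> FusionModel:
    """Fit the full fusion model from truth-bearing observations.

    Per partition: pooled truth-bearing distance matrix, powerset
    expectations, and the optimal cutoff.  Partitions with no calls anywhere
    get the pass-nothing marker.  The result is deterministic and invariant
    to observation order (weights permute with their observations).
    """
    if not observations:
        raise DataError("training requires at least one observation")
    if any(obs.truth is None for obs in observations):
        raise DataError("training requires truth callsets in every observation")
    order = sorted(range(len(observations)), key=lambda i: observations[i].sample_id)
    if weights is None:
        weights = [1.0] * len(observations)
    observations = [observations[i] for i in order]
    weights = [weights[i] for i in order]
    if bins is None:
        bins = BinScheme.default()
    metric = MetricKind(metric)
    caller_ids = observations[0].caller_ids

    # pre-partition every callset once
    parts: list[dict[int, dict]] = []
    truth_parts: list[dict] = []
    for obs in observations:
        parts.append({cid: partition(cs, bins) for cid, cs in obs.callsets.items()})
        truth_parts.append(partition(obs.truth, bins))

    partitions: dict[PartitionKey, PartitionModel] = {}
    for key in bins.keys():
        has_data = any(
            key in truth_parts[y]
            or any(key in parts[y][cid] for cid in caller_ids)
            for y in range(len(observations))
        )
        if not has_data:
            partitions[key] = PartitionModel(
                key, GroupExpectation(key, {}), EMPTY_ALPHA, 0.0, empty=True
            )
            continue
        restricted = [
            Observation(
                obs.sample_id,
                {
                    cid: parts[y][cid].get(key, obs.callsets[cid].with_calls([]))
                    for cid in caller_ids
                },
                truth=truth_parts[y].get(key, obs.truth.with_calls([])),
            )
            for y, obs in enumerate(observations)
        ]
        dmat = pooled_distance_matrix(
            restricted, weights, metric, include_truth=True
        )
        expectations = all_group_expectations(dmat, key)
        alpha, fitted = fit_cutoff(
            restricted, expectations, key, bins, weights, metric, search
        )
        partitions[key] = PartitionModel(key, expectations, alpha, fitted)

    spreads = estimate_breakpoint_spreads(observations)
    caller_distance = pooled_distance_matrix(
        observations, weights, metric, include_truth=False
    )
    meta = dict(metadata or {})
    meta.setdefault("sample_ids", [obs.sample_id for obs in observations])
    meta.setdefault("weights", list(weights))
    meta.setdefault("metric", metric.value)
    return FusionModel(
        caller_ids=list(caller_ids),
        bins=bins,
        partitions=partitions,
        spreads=spreads,
        caller_distance=caller_distance,
        metric=metric,
        metadata=meta,
    )


def model_to_dict(model: FusionModel) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "caller_ids": model.caller_ids,
        "metric": model.metric.value,
        "bins": {t: list(e) for t, e in model.bins.edges.items()},
        "partitions": [
            {
                "sv_type": key.sv_type,
                "bin_index": key.bin_index,
                "alpha": pm.alpha,
                "fitted_distance": pm.fitted_distance,
                "empty": pm.empty,
                "expectations": {
                    _subset_key(g): v for g, v in sorted(
                        pm.expectations.table.items(), key=lambda kv: _subset_key(kv[0])
                    )
                },
            }
            for key, pm in sorted(model.partitions.items())
        ],
        "spreads": {
            "sigma_l": {str(k): v for k, v in model.spreads.sigma_l.items()},
            "sigma_r": {str(k): v for k, v in model.spreads.sigma_r.items()},
            "n_l": {str(k): v for k, v in model.spreads.n_l.items()},
            "n_r": {str(k): v for k, v in model.spreads.n_r.items()},
        },
        "caller_distance": model.caller_distance.to_dict(),
        "metadata": model.metadata,
    }


def model_from_dict(d: dict) -> FusionModel:
    if d.get("schema") != MODEL_SCHEMA:
        raise ModelVersionError(
            f"model schema {d.get('schema')!r} is not {MODEL_SCHEMA!r}"
        )
    bins = BinScheme({t: tuple(e) for t, e in d["bins"].items()})
    partitions = {}
    for p in d["partitions"]:
        key = PartitionKey(p["sv_type"], p["bin_index"])
        table = {_parse_subset(k): v for k, v in p["expectations"].items()}
        partitions[key] = PartitionModel(
            key,
            GroupExpectation(key, table),
            p["alpha"],
            p["fitted_distance"],
            p["empty"],
        )
    sp = d["spreads"]
    spreads = BreakpointSpread(
        {int(k): v for k, v in sp["sigma_l"].items()},
        {int(k): v for k, v in sp["sigma_r"].items()},
        {int(k): v for k, v in sp["n_l"].items()},
        {int(k): v for k, v in sp["n_r"].items()},
    )
    return FusionModel(
        caller_ids=list(d["caller_ids"]),
        bins=bins,
        partitions=partitions,
        spreads=spreads,
        caller_distance=DistanceMatrix.from_dict(d["caller_distance"]),
        metric=MetricKind(d["metric"]),
        metadata=d.get("metadata", {}),
    )


def save_model(model: FusionModel, path) -> None:
    """Serialise the model as versioned JSON (lossless round-trip)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> FusionModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def model_digest(model: FusionModel) -> str:
    """Stable content digest of a model (metadata included)."""
    payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def expectation_table_tsv(model: FusionModel, path) -> None:
    """Export every per-bin subset expectation as a flat TSV."""
    with open(path, "w") as fh:
        fh.write("sv_type\tbin_index\tbin_lo\tbin_hi\tcallers\texpectation\talpha\n")
        for key, pm in sorted(model.partitions.items()):
            lo, hi = model.bins.bin_bounds(key)
            for g, v in sorted(pm.expectations.table.items(), key=lambda kv: _subset_key(kv[0])):
                fh.write(
                    f"{key.sv_type}\t{key.bin_index}\t{lo}\t{hi}\t"
                    f"{_subset_key(g)}\t{v:.6g}\t{pm.alpha:.6g}\n"
                )
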