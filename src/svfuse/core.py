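"""Call/callset data model, filtering, masking and partitioning.

Coordinates are flattened, 0-based and inclusive throughout; conversion to
and from VCF/BED conventions happens only at the I/O boundary (:mod:`svfuse.vcf_io`).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

from svfuse.errors import DataError
from svfuse.intervals import overlap_bp, validate_disjoint_sorted

log = logging.getLogger(__name__)

SV_TYPES = ("INS", "DEL", "DUP", "INV", "TRA")

#: caller id reserved for truth callsets in distance matrices
TRUTH_ID = -1

#: FILTER values treated as passing
PASSING_FILTERS = frozenset({"PASS", ".", ""})


@dataclass(frozen=True)
class Call:
    """One SV event on the flattened genome.

    ``s_start``/``s_end`` are the source interval (inclusive);
    ``d_start``/``d_end`` the destination, equal to the source for non-TRA
    types.  ``a_seq`` carries the alternate sequence for insertions.
    """

    s_start: int
    s_end: int
    sv_type: str
    d_start: int = -1
    d_end: int = -1
    a_seq: str = ""
    caller_id: int = 0
    filter_value: str = "."
    sample_id: str = ""

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise DataError(f"unknown sv_type {self.sv_type!r}")
        if self.s_start > self.s_end:
            raise DataError(f"s_start {self.s_start} > s_end {self.s_end}")
        if self.d_start == -1 and self.d_end == -1:
            object.__setattr__(self, "d_start", self.s_start)
            object.__setattr__(self, "d_end", self.s_end)
        if self.d_start > self.d_end:
            raise DataError(f"d_start {self.d_start} > d_end {self.d_end}")

    @property
    def size(self) -> int:
        return self.s_end - self.s_start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)


@dataclass
class Callset:
    """All calls of one caller on one sample, kept sorted by coordinate."""

    caller_id: int
    sample_id: str
    calls: list[Call] = field(default_factory=list)

    def __post_init__(self):
        self.calls = sorted(self.calls, key=lambda c: (c.s_start, c.s_end))
        for c in self.calls:
            if c.caller_id != self.caller_id or c.sample_id != self.sample_id:
                raise DataError(
                    f"call tagged ({c.caller_id}, {c.sample_id!r}) in callset "
                    f"({self.caller_id}, {self.sample_id!r})"
                )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def add(self, call: Call) -> None:
        if call.caller_id != self.caller_id or call.sample_id != self.sample_id:
            raise DataError("call does not belong to this callset")
        self.calls.append(call)
        self.calls.sort(key=lambda c: (c.s_start, c.s_end))

    def with_calls(self, calls) -> "Callset":
        return Callset(self.caller_id, self.sample_id, list(calls))

    def intervals(self) -> list[tuple[int, int]]:
        return [c.interval for c in self.calls]


def make_callset(caller_id, sample_id, triples) -> Callset:
    """Convenience constructor from ``(s_start, s_end, sv_type)`` triples."""
    calls = [
        Call(s, e, t, caller_id=caller_id, sample_id=sample_id) for s, e, t in triples
    ]
    return Callset(caller_id, sample_id, calls)


@dataclass
class Observation:
    """One sample's callsets across all callers, plus an optional truth set."""

    sample_id: str
    callsets: dict[int, Callset]
    truth: Callset | None = None

    def __post_init__(self):
        for cid, cs in self.callsets.items():
            if cs.caller_id != cid:
                raise DataError(f"callset keyed {cid} has caller_id {cs.caller_id}")
            if cs.sample_id != self.sample_id:
                raise DataError("callset sample_id mismatch in observation")
        if self.truth is not None and self.truth.sample_id != self.sample_id:
            raise DataError("truth sample_id mismatch in observation")

    @property
    def caller_ids(self) -> list[int]:
        return sorted(self.callsets)


@dataclass(frozen=True, order=True)
class PartitionKey:
    sv_type: str
    bin_index: int


DEFAULT_BIN_EDGES = (50, 100, 250, 500, 1000, 5000, 10000, 50000, 100000, 1000000, 100000001)


@dataclass(frozen=True)
class BinScheme:
    """Per-type half-open size bins ``[e_k, e_{k+1})`` spanning 50 bp to >=100 Mbp."""

    edges: dict[str, tuple[int, ...]]

    def __post_init__(self):
        for t, e in self.edges.items():
            e = tuple(int(x) for x in e)
            if list(e) != sorted(set(e)):
                raise DataError(f"bin edges for {t} not strictly increasing")
            if e[0] < 50:
                raise DataError(f"first bin edge for {t} must be >= 50")
            if e[-1] < 100_000_000:
                raise DataError(f"last bin edge for {t} must be >= 100 Mbp")
            object.__getattribute__(self, "edges")[t] = e

    @classmethod
    def default(cls, types=("DEL", "DUP", "INV")) -> "BinScheme":
        return cls({t: DEFAULT_BIN_EDGES for t in types})

    @property
    def types(self) -> list[str]:
        return sorted(self.edges)

    def n_bins(self, sv_type: str) -> int:
        return len(self.edges[sv_type]) - 1

    def bin_of(self, sv_type: str, size: int) -> int | None:
        """Bin index for a size, or ``None`` when the size is out of range."""
        e = self.edges.get(sv_type)
        if e is None:
            return None
        if not e[0] <= size < e[-1]:
            return None
        return bisect_right(e, size) - 1

    def bin_bounds(self, key: PartitionKey) -> tuple[int, int]:
        e = self.edges[key.sv_type]
        return e[key.bin_index], e[key.bin_index + 1]

    def keys(self) -> list[PartitionKey]:
        return [
            PartitionKey(t, k) for t in self.types for k in range(self.n_bins(t))
        ]


def standard_filter(
    callset: Callset,
    min_size: int = 50,
    types=frozenset({"DEL", "DUP", "INV"}),
) -> Callset:
    """Keep calls with size >= ``min_size``, a supported type and a passing FILTER."""
    kept = [
        c
        for c in callset
        if c.size >= min_size and c.sv_type in types and c.filter_value in PASSING_FILTERS
    ]
    return callset.with_calls(kept)


def apply_mask(callset: Callset, mask, overlap_threshold: float = 0.5) -> Callset:
    """Drop calls whose masked base-pair fraction exceeds ``overlap_threshold``.

    ``mask`` is a sorted, disjoint list of flattened inclusive intervals.
    """
    validate_disjoint_sorted(mask)
    if not mask:
        return callset.with_calls(callset.calls)
    starts = [s for s, _ in mask]
    kept = []
    for c in callset:
        i = max(0, bisect_right(starts, c.s_start) - 1)
        masked = 0
        while i < len(mask) and mask[i][0] <= c.s_end:
            masked += overlap_bp(c.s_start, c.s_end, mask[i][0], mask[i][1])
            i += 1
        if masked / c.size <= overlap_threshold:
            kept.append(c)
    return callset.with_calls(kept)


def partition(callset: Callset, bins: BinScheme) -> dict[PartitionKey, Callset]:
    """Segregate a filtered callset by (sv_type, size bin).

    Every call lands in exactly one partition; calls whose size falls outside
    the scheme are dropped with a logged count.
    """
    out: dict[PartitionKey, list[Call]] = {}
    dropped = 0
    for c in callset:
        k = bins.bin_of(c.sv_type, c.size)
        if k is None:
            dropped += 1
            continue
        out.setdefault(PartitionKey(c.sv_type, k), []).append(c)
    if dropped:
        log.info(
            "partition: %d call(s) outside the bin scheme dropped (caller %d, sample %s)",
            dropped, callset.caller_id, callset.sample_id,
        )
    return {k: callset.with_calls(v) for k, v in sorted(out.items())}
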