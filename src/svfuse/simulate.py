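"""Synthetic truth sets and correlated multi-caller callsets.

Every other module is testable against this generator: truth events with a
controlled type/size distribution, per-caller sensitivity by (type, size
bin), Gaussian breakpoint jitter, false positives at a per-Mbp rate, and
optional shared false-positive pools that induce pairwise caller
correlation.  All output is a pure function of (spec, master seed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from bisect import bisect_right, insort

import numpy as np

from svfuse.core import TRUTH_ID, BinScheme, Call, Callset, Observation
from svfuse.errors import DataError
from svfuse.genome import Genome

log = logging.getLogger(__name__)

MIN_SV_SIZE = 50


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one simulated caller.

    ``sensitivity`` maps ``(sv_type, bin_index)`` to detection probability;
    ``default_sensitivity`` covers unlisted cells.  ``fp_rate`` is expected
    false positives per Mbp per sv_type.  Callers sharing ``fp_pool`` draw
    false positives from one pregenerated pool and are therefore correlated.
    """

    caller_id: int
    name: str = ""
    sensitivity: dict = field(default_factory=dict)
    default_sensitivity: float = 0.5
    fp_rate: float = 0.5
    sigma_l: float = 10.0
    sigma_r: float = 10.0
    fp_pool: int | None = None
    size_distortion: float = 1.0

    def __post_init__(self):
        if self.default_sensitivity < 0 or self.fp_rate < 0:
            raise DataError("sensitivities and rates must be >= 0")
        if self.sigma_l < 0 or self.sigma_r < 0:
            raise DataError("jitter sigmas must be >= 0")

    def sens(self, sv_type: str, bin_index: int) -> float:
        return self.sensitivity.get((sv_type, bin_index), self.default_sensitivity)

    def to_dict(self) -> dict:
        return {
            "caller_id": self.caller_id,
            "name": self.name,
            "sensitivity": [[t, b, v] for (t, b), v in sorted(self.sensitivity.items())],
            "default_sensitivity": self.default_sensitivity,
            "fp_rate": self.fp_rate,
            "sigma_l": self.sigma_l,
            "sigma_r": self.sigma_r,
            "fp_pool": self.fp_pool,
            "size_distortion": self.size_distortion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CallerProfile":
        d = dict(d)
        d["sensitivity"] = {(t, b): v for t, b, v in d.get("sensitivity", [])}
        return cls(**d)


@dataclass(frozen=True)
class CohortSpec:
    genome: Genome
    n_samples: int = 6
    truth_count: int = 500
    type_mix: tuple = (("DEL", 0.6), ("DUP", 0.25), ("INV", 0.15))
    size_range: tuple[int, int] = (MIN_SV_SIZE, 50_000)
    profiles: tuple[CallerProfile, ...] = ()
    seed: int = 0
    bins: BinScheme = field(default_factory=BinScheme.default)

    def __post_init__(self):
        if self.n_samples <= 0 or self.truth_count <= 0:
            raise DataError("sample and truth counts must be positive")
        if abs(sum(p for _, p in self.type_mix) - 1.0) > 1e-9:
            raise DataError("type-mix proportions must sum to 1")
        if self.size_range[0] < MIN_SV_SIZE:
            raise DataError(f"minimum simulated size is {MIN_SV_SIZE} bp")

    def to_dict(self) -> dict:
        return {
            "genome": list(self.genome.contigs),
            "n_samples": self.n_samples,
            "truth_count": self.truth_count,
            "type_mix": [list(x) for x in self.type_mix],
            "size_range": list(self.size_range),
            "profiles": [p.to_dict() for p in self.profiles],
            "seed": self.seed,
            "bins": {t: list(e) for t, e in self.bins.edges.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            genome=Genome.from_pairs(d["genome"]),
            n_samples=d["n_samples"],
            truth_count=d["truth_count"],
            type_mix=tuple((t, p) for t, p in d["type_mix"]),
            size_range=tuple(d["size_range"]),
            profiles=tuple(CallerProfile.from_dict(p) for p in d["profiles"]),
            seed=d["seed"],
            bins=BinScheme({t: tuple(e) for t, e in d["bins"].items()}),
        )


def _rng(*streams: int) -> np.random.Generator:
    return np.random.default_rng(list(streams))


def _draw_size(rng, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _place_interval(rng, genome: Genome, size: int, occupied_starts, occupied, retries: int):
    """Uniform placement of an interval avoiding overlap and contig breaks."""
    for _ in range(retries):
        start = int(rng.integers(0, genome.size - size))
        end = start + size - 1
        lo, hi = genome.contig_span(start)
        if end > hi:
            continue
        i = bisect_right(occupied_starts, start)
        if i > 0 and occupied[i - 1][1] >= start:
            continue
        if i < len(occupied) and occupied[i][0] <= end:
            continue
        insort(occupied_starts, start)
        occupied.insert(bisect_right(occupied_starts, start) - 1, (start, end))
        return start, end
    return None


def simulate_truth(spec: CohortSpec, sample_index: int) -> Callset:
    """Non-overlapping truth events for one sample, deterministic per seed."""
    rng = _rng(spec.seed, 11, sample_index)
    types = [t for t, _ in spec.type_mix]
    probs = [p for _, p in spec.type_mix]
    sample_id = f"sample_{sample_index}"
    occupied: list[tuple[int, int]] = []
    occupied_starts: list[int] = []
    calls = []
    lo, hi = spec.size_range
    for _ in range(spec.truth_count):
        sv_type = types[int(rng.choice(len(types), p=probs))]
        size = max(MIN_SV_SIZE, _draw_size(rng, lo, hi))
        placed = _place_interval(rng, spec.genome, size, occupied_starts, occupied, 1000)
        if placed is None:
            raise DataError(
                "could not place all truth events without overlap; use a larger genome"
            )
        calls.append(
            Call(placed[0], placed[1], sv_type, caller_id=TRUTH_ID, sample_id=sample_id)
        )
    return Callset(TRUTH_ID, sample_id, calls)


def _fp_pool_calls(spec: CohortSpec, sample_index: int, pool_id: int, count: int) -> list:
    """Deterministic pregenerated pool of FP events shared by pool-mates."""
    rng = _rng(spec.seed, 17, sample_index, pool_id)
    types = [t for t, _ in spec.type_mix]
    probs = [p for _, p in spec.type_mix]
    lo, hi = spec.size_range
    out = []
    for _ in range(count):
        sv_type = types[int(rng.choice(len(types), p=probs))]
        size = max(MIN_SV_SIZE, _draw_size(rng, lo, hi))
        start = int(rng.integers(0, spec.genome.size - size))
        clo, chi = spec.genome.contig_span(start)
        end = min(start + size - 1, chi)
        if end - start + 1 < MIN_SV_SIZE:
            end = min(start + MIN_SV_SIZE - 1, chi)
            start = end - MIN_SV_SIZE + 1
        out.append((start, end, sv_type))
    return out


def simulate_caller(
    truth: Callset,
    profile: CallerProfile,
    spec: CohortSpec,
    sample_index: int,
) -> Callset:
    """Corrupt a truth set according to one caller's error profile."""
    rng = _rng(spec.seed, 13, sample_index, profile.caller_id)
    genome = spec.genome
    calls = []
    for t in truth:
        bin_index = spec.bins.bin_of(t.sv_type, t.size)
        p = profile.sens(t.sv_type, bin_index if bin_index is not None else -1)
        if rng.random() >= p:
            continue
        size = max(MIN_SV_SIZE, int(round(t.size * profile.size_distortion)))
        start = t.s_start + int(round(rng.normal(0.0, profile.sigma_l)))
        end = t.s_start + size - 1 + int(round(rng.normal(0.0, profile.sigma_r)))
        clo, chi = genome.contig_span(t.s_start)
        start = min(max(start, clo), chi)
        end = min(max(end, clo), chi)
        if end - start + 1 < MIN_SV_SIZE:
            end = min(start + MIN_SV_SIZE - 1, chi)
            start = end - MIN_SV_SIZE + 1
        calls.append(
            Call(start, end, t.sv_type, caller_id=profile.caller_id, sample_id=truth.sample_id)
        )
    # false positives
    lam = profile.fp_rate * genome.size / 1e6
    n_fp = int(rng.poisson(lam)) if lam > 0 else 0
    if n_fp:
        if profile.fp_pool is not None:
            pool_size = max(n_fp, int(4 * lam) + 20)
            pool = _fp_pool_calls(spec, sample_index, profile.fp_pool, pool_size)
            fp_events = pool[:n_fp]
        else:
            fp_events = _fp_pool_calls(
                spec, sample_index, 100_000 + profile.caller_id, n_fp
            )
        for start, end, sv_type in fp_events:
            calls.append(
                Call(start, end, sv_type, caller_id=profile.caller_id,
                     sample_id=truth.sample_id)
            )
    return Callset(profile.caller_id, truth.sample_id, calls)


def simulate_cohort(spec: CohortSpec) -> list[Observation]:
    """Per-sample truth plus per-caller corrupted callsets for the cohort."""
    if not spec.profiles:
        raise DataError("cohort spec has no caller profiles")
    observations = []
    for i in range(spec.n_samples):
        truth = simulate_truth(spec, i)
        callsets = {
            p.caller_id: simulate_caller(truth, p, spec, i) for p in spec.profiles
        }
        observations.append(Observation(truth.sample_id, callsets, truth=truth))
    return observations


def default_genome(n_contigs: int = 2, contig_length: int = 25_000_000) -> Genome:
    return Genome.from_pairs(
        (f"chr{k + 1}", contig_length) for k in range(n_contigs)
    )


def complementary_profiles(
    n_callers: int = 4,
    bins: BinScheme | None = None,
    good_sens: float = 0.98,
    poor_sens: float = 0.02,
    fp_rate: float = 0.3,
    sigmas=(5.0, 12.0, 20.0, 30.0),
) -> tuple[CallerProfile, ...]:
    """Callers that are near-perfect on disjoint (type, bin) blocks.

    The (type, bin) grid is dealt round-robin to the callers, so each caller
    dominates its own block and is nearly blind elsewhere — the construction
    used to demonstrate ensemble dominance over any single caller.
    """
    bins = bins or BinScheme.default()
    cells = [(k.sv_type, k.bin_index) for k in bins.keys()]
    profiles = []
    for c in range(n_callers):
        sens = {
            cell: (good_sens if i % n_callers == c else poor_sens)
            for i, cell in enumerate(cells)
        }
        profiles.append(
            CallerProfile(
                caller_id=c + 1,
                name=f"caller{c + 1}",
                sensitivity=sens,
                default_sensitivity=poor_sens,
                fp_rate=fp_rate,
                sigma_l=sigmas[c % len(sigmas)],
                sigma_r=sigmas[(c + 1) % len(sigmas)],
                fp_pool=None,
            )
        )
    return tuple(profiles)


def save_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        return CohortSpec.from_dict(json.load(fh))
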