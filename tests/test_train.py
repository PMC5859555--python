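import itertools

import numpy as np
import pytest

from svfuse.core import TRUTH_ID, BinScheme, Observation, PartitionKey
from svfuse.errors import DataError, ModelVersionError
from svfuse.similarity import DistanceMatrix, MetricKind, jaccard
from svfuse.train import (
    EMPTY_ALPHA,
    GroupExpectation,
    all_group_expectations,
    estimate_breakpoint_spreads,
    fit_cutoff,
    fuse_segments,
    group_expectation,
    load_model,
    model_digest,
    model_from_dict,
    model_to_dict,
    project,
    save_model,
    train,
    update_expectation_with_truth,
    update_expectation_without_truth,
)

from conftest import bp_set, cs, truth_cs


def dmat(ids, entries, metric=MetricKind.J):
    """DistanceMatrix from a dict of (i, j) -> distance."""
    n = len(ids)
    m = np.zeros((n, n))
    pos = {c: k for k, c in enumerate(ids)}
    for (i, j), v in entries.items():
        m[pos[i], pos[j]] = v
        m[pos[j], pos[i]] = v
    return DistanceMatrix(ids, m, metric)


class TestGroupExpectation:
    def test_singleton_reduces_to_accuracy(self):
        d = dmat([1, TRUTH_ID], {(1, TRUTH_ID): 0.2})
        assert group_expectation({1}, d) == pytest.approx(0.8)

    def test_identical_perfect_pair_is_zero(self):
        d = dmat([1, 2, TRUTH_ID],
                 {(1, TRUTH_ID): 0.0, (2, TRUTH_ID): 0.0, (1, 2): 0.0})
        assert group_expectation({1, 2}, d) == 0.0

    def test_hand_worked_pair(self):
        # (0.8 * 0.5) * (0.6 * 0.5) = 0.12
        d = dmat([1, 2, TRUTH_ID],
                 {(1, TRUTH_ID): 0.2, (2, TRUTH_ID): 0.4, (1, 2): 0.5})
        assert group_expectation({1, 2}, d) == pytest.approx(0.12)

    def test_empty_group_rejected(self):
        d = dmat([1, TRUTH_ID], {(1, TRUTH_ID): 0.2})
        with pytest.raises(DataError):
            group_expectation(set(), d)

    def test_requires_truth_row(self):
        d = dmat([1, 2], {(1, 2): 0.5})
        with pytest.raises(DataError):
            group_expectation({1, 2}, d)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        ids = [1, 2, 3, 4, TRUTH_ID]
        entries = {
            (i, j): float(rng.uniform(0, 1))
            for i, j in itertools.combinations(ids, 2)
        }
        d = dmat(ids, entries)
        baseline = group_expectation({1, 2, 3, 4}, d)
        for perm in itertools.permutations([1, 2, 3, 4]):
            assert group_expectation(frozenset(perm), d) == pytest.approx(baseline)

    def test_clone_never_raises_expectation(self):
        # adding a caller identical to an existing member cannot raise E
        rng = np.random.default_rng(10)
        for _ in range(20):
            ids = [1, 2, 3, TRUTH_ID]
            entries = {
                (i, j): float(rng.uniform(0.05, 0.95))
                for i, j in itertools.combinations(ids, 2)
            }
            d = dmat(ids, entries)
            # clone caller 4 := caller 1
            ids5 = [1, 2, 3, 4, TRUTH_ID]
            e5 = dict(entries)
            for other in [2, 3, TRUTH_ID]:
                key = (1, other) if (1, other) in entries else (other, 1)
                e5[(4, other)] = entries[key]
            e5[(1, 4)] = 0.0
            d5 = dmat(ids5, e5)
            for g in [{1, 2}, {1, 3}, {1, 2, 3}]:
                assert group_expectation(g | {4}, d5) <= group_expectation(g, d) + 1e-12

    def test_perfect_caller_singleton_is_one(self):
        d = dmat([1, TRUTH_ID], {(1, TRUTH_ID): 0.0})
        assert group_expectation({1}, d) == 1.0


class TestAllGroupExpectations:
    def test_counts(self):
        for n, expected in [(3, 7), (8, 255)]:
            ids = list(range(1, n + 1)) + [TRUTH_ID]
            rng = np.random.default_rng(n)
            entries = {
                (i, j): float(rng.uniform(0, 1))
                for i, j in itertools.combinations(ids, 2)
            }
            ge = all_group_expectations(dmat(ids, entries))
            assert len(ge.table) == expected
            assert frozenset(range(1, n + 1)) in ge.table

    def test_ceiling(self):
        ids = list(range(1, 14)) + [TRUTH_ID]
        d = DistanceMatrix(ids, np.zeros((len(ids), len(ids))), MetricKind.J)
        with pytest.raises(DataError, match="ceiling"):
            all_group_expectations(d)


def _two_caller_obs(a, b, t, sample_id="s"):
    return Observation(
        sample_id,
        {1: cs(1, a, sample_id), 2: cs(2, b, sample_id)},
        truth=truth_cs(t, sample_id),
    )


class TestUpdates:
    def setup_method(self):
        self.prior = [
            _two_caller_obs([(0, 799, "DEL")], [(0, 999, "DEL")],
                            [(0, 999, "DEL")], "s1")
        ]

    def test_zero_new_obs_reduces_to_baseline(self):
        from svfuse.similarity import pooled_distance_matrix

        baseline = all_group_expectations(
            pooled_distance_matrix(self.prior, include_truth=True)
        )
        up_a = update_expectation_with_truth(self.prior, [1.0], [], [])
        up_b = update_expectation_without_truth(self.prior, [1.0], [], [])
        assert up_a.table == baseline.table
        assert up_b.table == baseline.table

    def test_duplicated_observations_unchanged(self):
        baseline = update_expectation_with_truth(self.prior, [1.0], [], [])
        dup = update_expectation_with_truth(
            self.prior, [1.0], list(self.prior), [1.0]
        )
        for g, v in baseline.table.items():
            assert dup.table[g] == pytest.approx(v)

    def test_with_truth_pooled_singleton(self):
        # prior delta(c1, t) = 0.2 (w=1), new delta = 0.6 (w=1) -> pooled 0.4
        new = [
            _two_caller_obs([(0, 399, "DEL")], [(0, 999, "DEL")],
                            [(0, 999, "DEL")], "s2")
        ]
        up = update_expectation_with_truth(self.prior, [1.0], new, [1.0])
        assert up.table[frozenset({1})] == pytest.approx(0.6)

    def test_without_truth_hand_worked(self):
        # truth distances stay from prior; caller-caller pool extends
        new = [
            Observation(
                "s2",
                {1: cs(1, [(0, 499, "DEL")], "s2"), 2: cs(2, [(0, 499, "DEL")], "s2")},
            )
        ]
        up = update_expectation_without_truth(self.prior, [1.0], new, [1.0])
        # prior: D(1,t)=0.2, D(2,t)=0.0, prior D(1,2)=0.2; new delta(1,2)=0 -> pooled 0.1
        expected_pair = (0.8 * 0.1) * (1.0 * 0.1)
        assert up.table[frozenset({1, 2})] == pytest.approx(expected_pair)
        # singletons keep prior truth distances
        assert up.table[frozenset({1})] == pytest.approx(0.8)

    def test_converging_callers_lose_value(self):
        # new truthless data where the callers become identical drags the
        # pooled dissimilarity down and with it the pair expectation
        identical = [
            Observation(
                "s2",
                {1: cs(1, [(0, 999, "DEL")], "s2"), 2: cs(2, [(0, 999, "DEL")], "s2")},
            )
        ]
        before = update_expectation_without_truth(self.prior, [1.0], [], [])
        after = update_expectation_without_truth(self.prior, [1.0], identical, [1.0])
        g = frozenset({1, 2})
        assert after.table[g] < before.table[g]


class TestProject:
    def _ge(self, values):
        return GroupExpectation(None, {frozenset(k): v for k, v in values.items()})

    def test_worked_overlap(self):
        ge = self._ge({(1,): 0.5, (2,): 0.6, (1, 2): 0.9})
        segs = project({1: cs(1, [(0, 99, "DEL")]), 2: cs(2, [(50, 149, "DEL")])}, ge)
        got = [(s.start, s.end, set(s.callers), s.expectation) for s in segs]
        assert got == [
            (0, 49, {1}, 0.5),
            (50, 99, {1, 2}, 0.9),
            (100, 149, {2}, 0.6),
        ]

    def test_breakpoints_recorded(self):
        ge = self._ge({(1,): 0.5, (2,): 0.6, (1, 2): 0.9})
        segs = project({1: cs(1, [(0, 99, "DEL")]), 2: cs(2, [(50, 149, "DEL")])}, ge)
        mid = segs[1]
        assert mid.breakpoints == {1: (0, 99), 2: (50, 149)}

    def test_single_call(self):
        ge = self._ge({(1,): 0.7})
        segs = project({1: cs(1, [(10, 59, "DEL")])}, ge)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end, segs[0].expectation) == (10, 59, 0.7)

    def test_identical_calls_three_callers(self):
        ge = self._ge({(1,): 0.1, (2,): 0.1, (3,): 0.1, (1, 2): 0.2, (1, 3): 0.2,
                       (2, 3): 0.2, (1, 2, 3): 0.8})
        sets = {i: cs(i, [(100, 199, "DEL")]) for i in (1, 2, 3)}
        segs = project(sets, ge)
        assert len(segs) == 1
        assert segs[0].callers == frozenset({1, 2, 3})
        assert segs[0].expectation == 0.8

    def test_conservation(self):
        rng = np.random.default_rng(12)
        ids = [1, 2, 3]
        sets = {}
        for i in ids:
            triples = []
            for _ in range(10):
                s = int(rng.integers(0, 5000))
                triples.append((s, s + int(rng.integers(50, 400)), "DEL"))
            sets[i] = cs(i, triples)
        table = {}
        for r in range(1, 4):
            for combo in itertools.combinations(ids, r):
                table[frozenset(combo)] = 0.5
        segs = project(sets, GroupExpectation(None, table))
        union = set()
        for c in sets.values():
            union |= bp_set(c)
        assert sum(s.length for s in segs) == len(union)
        # segments disjoint and sorted
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start

    def test_mixed_types_rejected(self):
        ge = self._ge({(1,): 0.5, (2,): 0.5, (1, 2): 0.5})
        with pytest.raises(DataError):
            project({1: cs(1, [(0, 99, "DEL")]), 2: cs(2, [(0, 99, "DUP")])}, ge)


class TestFitCutoff:
    def _oracle(self, observations, expectations, key, bins, weights, metric):
        """Independent scan: bp-set proposals, literal Jaccard, tie to larger."""
        from svfuse.core import partition as part

        assert metric is MetricKind.J
        per_obs = []
        for obs in observations:
            parts = {
                cid: part(csx, bins).get(key, csx.with_calls([]))
                for cid, csx in obs.callsets.items()
            }
            segs = project(parts, expectations)
            tr = part(obs.truth, bins).get(key, obs.truth.with_calls([]))
            per_obs.append((segs, bp_set(tr)))
        best = None
        for p in sorted(set(expectations.table.values()) | {0.0}):
            num = 0.0
            for (segs, tset), w in zip(per_obs, weights):
                kept = set()
                for s in segs:
                    if s.expectation >= p:
                        kept.update(range(s.start, s.end + 1))
                union = len(kept | tset)
                j = 1.0 if union == 0 else len(kept & tset) / union
                num += w * (1.0 - j)
            d = num / sum(weights)
            if best is None or d < best[1] or (d == best[1] and p > best[0]):
                best = (p, d)
        return best

    def test_matches_bruteforce_on_random_fixtures(self):
        bins = BinScheme.default()
        key = PartitionKey("DEL", 0)  # sizes [50, 100)
        rng = np.random.default_rng(77)
        for trial in range(20):
            n_callers = 3 + trial % 2
            observations = []
            for y in range(2):
                sid = f"s{y}"
                truth_triples = []
                pos = 0
                for _ in range(6):
                    pos += int(rng.integers(200, 600))
                    truth_triples.append((pos, pos + int(rng.integers(50, 99)), "DEL"))
                callsets = {}
                for cid in range(1, n_callers + 1):
                    triples = []
                    for (s, e, t) in truth_triples:
                        if rng.random() < 0.7:
                            js = int(rng.integers(-10, 11))
                            triples.append((s + js, min(e + js, s + js + 98), t))
                    if rng.random() < 0.5:
                        fp = int(rng.integers(5000, 8000))
                        triples.append((fp, fp + 60, "DEL"))
                    callsets[cid] = cs(cid, triples, sid)
                observations.append(
                    Observation(sid, callsets, truth=truth_cs(truth_triples, sid))
                )
            from svfuse.similarity import pooled_distance_matrix

            dmat_ = pooled_distance_matrix(
                observations, include_truth=True, key=key, bins=bins
            )
            ge = all_group_expectations(dmat_, key)
            weights = [1.0, 1.0]
            alpha, dist = fit_cutoff(observations, ge, key, bins, weights)
            o_alpha, o_dist = self._oracle(observations, ge, key, bins, weights,
                                           MetricKind.J)
            assert alpha == pytest.approx(o_alpha)
            assert dist == pytest.approx(o_dist)

    def test_exhaustive_equals_em(self):
        bins = BinScheme.default()
        key = PartitionKey("DEL", 0)
        rng = np.random.default_rng(5)
        sid = "s0"
        truth_triples = [(i * 500, i * 500 + 70, "DEL") for i in range(8)]
        callsets = {}
        for cid in range(1, 5):
            triples = [t for t in truth_triples if rng.random() < 0.8]
            callsets[cid] = cs(cid, triples, sid)
        obs = [Observation(sid, callsets, truth=truth_cs(truth_triples, sid))]
        from svfuse.similarity import pooled_distance_matrix

        ge = all_group_expectations(
            pooled_distance_matrix(obs, include_truth=True, key=key, bins=bins), key
        )
        a1, d1 = fit_cutoff(obs, ge, key, bins, search="exhaustive")
        a2, d2 = fit_cutoff(obs, ge, key, bins, search="em")
        assert (a1, d1) == (a2, d2)

    def test_all_identical_to_truth_tie_breaks_large(self):
        bins = BinScheme.default()
        key = PartitionKey("DEL", 1)  # sizes [100, 250)
        triples = [(0, 149, "DEL"), (1000, 1149, "DEL")]
        obs = [
            Observation(
                "s",
                {1: cs(1, triples), 2: cs(2, triples)},
                truth=truth_cs(triples),
            )
        ]
        from svfuse.similarity import pooled_distance_matrix

        ge = all_group_expectations(
            pooled_distance_matrix(obs, include_truth=True, key=key, bins=bins), key
        )
        alpha, dist = fit_cutoff(obs, ge, key, bins)
        assert dist == 0.0
        # every p at or below the full-group E gives distance 0; largest wins
        full_e = ge.table[frozenset({1, 2})]
        achievable = [p for p in ge.candidates() if p <= full_e]
        assert alpha == max(achievable)


class TestBreakpointSpreads:
    def test_exact_breakpoints_zero_sigma(self):
        triples = [(0, 99, "DEL"), (500, 699, "DEL"), (1000, 1099, "DEL")]
        obs = [Observation("s", {1: cs(1, triples)}, truth=truth_cs(triples))]
        sp = estimate_breakpoint_spreads(obs)
        assert sp.sigma_l[1] == 0.0
        assert sp.sigma_r[1] == 0.0
        assert sp.n_l[1] == 3

    def test_known_offsets(self):
        truth = [(100, 199, "DEL"), (500, 599, "DEL")]
        calls = [(90, 199, "DEL"), (510, 599, "DEL")]  # left offsets -10, +10
        obs = [Observation("s", {1: cs(1, calls)}, truth=truth_cs(truth))]
        sp = estimate_breakpoint_spreads(obs)
        assert sp.sigma_l[1] == pytest.approx(np.std([-10, 10], ddof=1))
        assert sp.sigma_r[1] == 0.0

    def test_no_overlaps(self):
        obs = [
            Observation(
                "s",
                {1: cs(1, [(5000, 5099, "DEL")])},
                truth=truth_cs([(0, 99, "DEL")]),
            )
        ]
        sp = estimate_breakpoint_spreads(obs)
        assert sp.n_l[1] == 0
        assert sp.sigma_l[1] == 0.0
        assert not sp.eligible(1)

    def test_largest_overlap_match(self):
        # call overlaps two truth calls; must match the larger-overlap one
        truth = [(0, 99, "DEL"), (90, 299, "DEL")]
        call = [(80, 280, "DEL")]
        obs = [Observation("s", {1: cs(1, call)}, truth=truth_cs(truth))]
        sp = estimate_breakpoint_spreads(obs)
        # matched to (90, 299): offsets are -10 (left), -19 (right); n=1 -> sigma 0
        assert sp.n_l[1] == 1
        assert sp.sigma_l[1] == 0.0


class TestTrainAndModelIO:
    def _fixture_obs(self, seed, n_obs=2):
        rng = np.random.default_rng(seed)
        observations = []
        for y in range(n_obs):
            sid = f"s{y}"
            truth_triples = []
            pos = 0
            for _ in range(12):
                pos += int(rng.integers(500, 1500))
                size = int(rng.integers(50, 5000))
                truth_triples.append((pos, pos + size - 1, "DEL"))
                pos += size
            callsets = {}
            for cid in (1, 2, 3):
                triples = []
                for (s, e, t) in truth_triples:
                    if rng.random() < 0.8:
                        j = int(rng.integers(-20, 21))
                        triples.append((max(0, s + j), e + j, t))
                callsets[cid] = cs(cid, triples, sid)
            observations.append(
                Observation(sid, callsets, truth=truth_cs(truth_triples, sid))
            )
        return observations

    def test_train_structure(self):
        obs = self._fixture_obs(1)
        model = train(obs)
        assert model.caller_ids == [1, 2, 3]
        for key, pm in model.partitions.items():
            if pm.empty:
                assert pm.alpha == EMPTY_ALPHA
                assert pm.expectations.table == {}
            else:
                assert len(pm.expectations.table) == 7
                assert pm.alpha in pm.expectations.candidates()

    def test_single_perfect_caller(self):
        triples = [(0, 99, "DEL"), (500, 599, "DEL")]
        obs = [Observation("s", {1: cs(1, triples)}, truth=truth_cs(triples))]
        model = train(obs)
        key = PartitionKey("DEL", 1)
        pm = model.partitions[key]
        assert pm.expectations.table[frozenset({1})] == 1.0
        assert pm.fitted_distance == 0.0

    def test_order_invariance(self):
        obs = self._fixture_obs(2, n_obs=3)
        m1 = train(obs)
        m2 = train(list(reversed(obs)))
        assert model_digest(m1) == model_digest(m2)

    def test_save_load_round_trip(self, tmp_path):
        obs = self._fixture_obs(3)
        model = train(obs)
        p = tmp_path / "model.json"
        save_model(model, p)
        loaded = load_model(p)
        assert model_to_dict(loaded) == model_to_dict(model)
        assert model_digest(loaded) == model_digest(model)

    def test_wrong_schema_rejected(self):
        with pytest.raises(ModelVersionError):
            model_from_dict({"schema": "svfuse-model-0"})

    def test_reloaded_model_drives_identical_discovery(self, tmp_path):
        from svfuse.discovery import discover

        obs = self._fixture_obs(4, n_obs=3)
        model = train(obs[:2])
        p = tmp_path / "model.json"
        save_model(model, p)
        loaded = load_model(p)
        out1 = discover(obs[2], model)
        out2 = discover(obs[2], loaded)
        assert [(c.start, c.end, c.sv_type) for c in out1] == \
               [(c.start, c.end, c.sv_type) for c in out2]

    def test_fuse_segments_length_weighted_mean(self):
        from svfuse.train import Segment

        segs = [
            Segment(0, 99, frozenset({1}), 0.9, "DEL", {1: (0, 99)}),
            Segment(100, 299, frozenset({2}), 0.3, "DEL", {2: (100, 299)}),
        ]
        fused = fuse_segments(segs)
        assert len(fused) == 1
        assert fused[0].expectation == pytest.approx((0.9 * 100 + 0.3 * 200) / 300)
        assert fused[0].callers == frozenset({1, 2})
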