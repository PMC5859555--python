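import numpy as np
import pytest

from svfuse.core import TRUTH_ID, Call, Callset
from svfuse.genome import Genome


@pytest.fixture
def tiny_genome():
    return Genome.from_pairs([("chr1", 5000), ("chr2", 5000)])


@pytest.fixture
def toy_genome():
    return Genome.from_pairs([("chr1", 1000)])


def cs(caller_id, triples, sample_id="s"):
    """Callset from (s_start, s_end, sv_type) triples."""
    return Callset(
        caller_id,
        sample_id,
        [Call(s, e, t, caller_id=caller_id, sample_id=sample_id) for s, e, t in triples],
    )


def truth_cs(triples, sample_id="s"):
    return cs(TRUTH_ID, triples, sample_id)


def bp_set(callset):
    """Literal base-pair set oracle."""
    out = set()
    for c in callset:
        out.update(range(c.s_start, c.s_end + 1))
    return out


def random_callset(rng, caller_id, genome_size=10_000, max_calls=8, sv_type="DEL",
                   sample_id="s"):
    n = int(rng.integers(0, max_calls + 1))
    triples = []
    for _ in range(n):
        s = int(rng.integers(0, genome_size - 1))
        e = min(genome_size - 1, s + int(rng.integers(1, 400)))
        triples.append((s, e, sv_type))
    return cs(caller_id, triples, sample_id)
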