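import random

import pytest

from maecall.formats import GenomicInterval, SequenceRecord


@pytest.fixture
def rng():
    return random.Random(20260927)


@pytest.fixture
def random_intervals(rng):
    """Factory for random interval sets on a couple of chromosomes."""

    def make(n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
        out = []
        for i in range(n):
            start = rng.randrange(0, max_pos)
            length = rng.randrange(1, max_len)
            out.append(GenomicInterval(rng.choice(chroms), start, start + length, name=f"iv{i}"))
        return out

    return make


@pytest.fixture
def random_genome(rng):
    """Factory for small random genomes as SequenceRecord lists."""

    def make(lengths=(2000, 1500), seed=None):
        r = random.Random(seed if seed is not None else rng.random())
        return [
            SequenceRecord(f"chr{i+1}", "".join(r.choice("ACGT") for _ in range(L)))
            for i, L in enumerate(lengths)
        ]

    return make
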