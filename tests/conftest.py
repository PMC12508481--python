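import numpy as np
import pytest

from trc_atlas.intervals import (
    GenomeAssembly,
    GenomeInterval,
    GenomeSequence,
    IntervalSet,
)


@pytest.fixture
def toy_assembly():
    return GenomeAssembly({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_genome(rng):
    """50 kb single-chromosome random genome at GC 0.5."""
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=50_000))
    return GenomeSequence.from_dict({"chr1": seq})


def make_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomeInterval(chrom, start, start + length))
    return IntervalSet(out)
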