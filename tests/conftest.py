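import numpy as np
import pytest

from oriskew.intervals import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_layout():
    """Two 10 kb chromosomes with one masked block on chrA."""
    return GenomeLayout(
        {"chrA": 10_000, "chrB": 10_000},
        IntervalSet([GenomicInterval("chrA", 4_000, 4_500)]),
    )


def ivset(*triples, label=None):
    """Shorthand: ivset(("chr1", 0, 10), ...)."""
    return IntervalSet(
        [GenomicInterval(c, s, e) for c, s, e in triples], label=label
    )
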