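import numpy as np
import pytest

from hetfit.popgen_stats import LocusAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def toy_alignment():
    """Four sequences, three sites, a ladder of derived alleles."""
    return LocusAlignment(
        "toy",
        ["AAA", "AAT", "ATT", "TTT"],
        ["popA", "popA", "popB", "popB"],
    )


@pytest.fixture
def two_pop_alignment():
    """2+2 alignment: site 1 a fixed difference, site 2 shared polymorphism."""
    return LocusAlignment(
        "twopop",
        ["AA", "AT", "TA", "TT"],
        ["popA", "popA", "popB", "popB"],
    )


def brute_force_pi(sequences, per_site=True):
    """O(n^2 L) pairwise-difference oracle with complete gap deletion."""
    keep = [
        j
        for j in range(len(sequences[0]))
        if all(s[j] not in "-N" for s in sequences)
    ]
    total = 0
    n = len(sequences)
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(sequences[i][c] != sequences[j][c] for c in keep)
    pairs = n * (n - 1) / 2
    mean_diffs = total / pairs
    return mean_diffs / len(keep) if per_site else mean_diffs
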