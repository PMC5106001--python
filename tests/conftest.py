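import itertools

import pytest
from hypothesis import settings

from maxentseq import AminoAcidProfile, load_codon_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return load_codon_table(1)


@pytest.fixture(scope="session")
def uniform_profile():
    return AminoAcidProfile.uniform()


def enumerate_expected_gc(profile, policy, table, length_aa):
    """Brute-force oracle: expected GC fraction of random sequences.

    Enumerates every amino-acid sequence over the profile's support and
    every codon assignment, weighting by profile and policy probabilities.
    Only tractable for small supports and lengths; kept independent of the
    analytic expectation it is used to check.
    """
    support = [aa for aa, f in profile.frequencies.items() if f > 0]
    total = 0.0
    for aa_seq in itertools.product(support, repeat=length_aa):
        p_aa = 1.0
        for a in aa_seq:
            p_aa *= profile.frequencies[a]
        fams = [table.synonymous_families[a] for a in aa_seq]
        for combo in itertools.product(*fams):
            p = p_aa
            for a, c in zip(aa_seq, combo):
                p *= policy.probability(a, c)
            gc = sum(table.gc_counts[c] for c in combo)
            total += p * gc / (3 * length_aa)
    return total


def enumerate_gc_distribution(aa_sequence, policy, table):
    """Brute-force oracle: exact pmf of the observed GC fraction for a
    fixed amino-acid sequence under a codon policy."""
    fams = [table.synonymous_families[a] for a in aa_sequence]
    pmf: dict[float, float] = {}
    n = 3 * len(aa_sequence)
    for combo in itertools.product(*fams):
        p = 1.0
        for a, c in zip(aa_sequence, combo):
            p *= policy.probability(a, c)
        gc = sum(table.gc_counts[c] for c in combo) / n
        pmf[gc] = pmf.get(gc, 0.0) + p
    return pmf
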