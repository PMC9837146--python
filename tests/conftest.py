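import numpy as np
import pytest

from complevo import Group, Individual, make_two_locus


@pytest.fixture
def valley_landscape():
    """Two-locus landscape with a local peak at 00, global peak at 11, and
    lethal single-mutant intermediates (f00=0.2, f01=f10=0, f11=1)."""
    return make_two_locus(0.2, 0.0, 0.0, 1.0)


@pytest.fixture
def flat_landscape():
    return make_two_locus(1.0, 1.0, 1.0, 1.0)


def make_group(*specs):
    """Build a Group from ('0110', deletion_count) tuples or genotype strings."""
    members = []
    for spec in specs:
        if isinstance(spec, tuple):
            alleles, dc = spec
        else:
            alleles, dc = spec, 0
        members.append(Individual(alleles, deletion_count=dc))
    return Group(members)


def random_group(rng, m, n, parasite_prob=0.0):
    alleles = rng.integers(0, 2, size=(m, n))
    members = []
    for row in alleles:
        if rng.random() < parasite_prob:
            members.append(Individual(row, deletion_count=int(rng.integers(1, n + 1))))
        else:
            members.append(Individual(row))
    # never all-parasite unless parasite_prob == 1
    if parasite_prob < 1.0 and all(ind.is_parasite for ind in members):
        members[0] = Individual(alleles[0], deletion_count=0)
    return Group(members)
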