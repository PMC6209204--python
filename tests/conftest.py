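import numpy as np
import pytest

from pedprio.pedigree import Individual, Pedigree


@pytest.fixture
def trio_file(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text(
        "FAM1 dad 0 0 1 HEALTHY\n"
        "FAM1 mum 0 0 2 HEALTHY\n"
        "FAM1 kid dad mum 1 BD_I\n"
    )
    return p


@pytest.fixture
def sib_pair_pedigree():
    """Two typed parents, two affected sibs."""
    return Pedigree(
        [
            Individual("f", sex="male"),
            Individual("m", sex="female"),
            Individual("s1", "f", "m", diagnosis="BD_I"),
            Individual("s2", "f", "m", diagnosis="BD_I"),
        ]
    )


@pytest.fixture
def sib_trio_pedigree():
    """Two parents, three sibs."""
    return Pedigree(
        [
            Individual("f"),
            Individual("m"),
            Individual("s1", "f", "m"),
            Individual("s2", "f", "m"),
            Individual("s3", "f", "m"),
        ]
    )


@pytest.fixture
def three_generation_pedigree():
    """Compact three-generation pedigree: founders 1,2 -> 3; 3 x 4 -> 5,6."""
    return Pedigree(
        [
            Individual("1"),
            Individual("2"),
            Individual("4"),
            Individual("3", "1", "2"),
            Individual("5", "3", "4"),
            Individual("6", "3", "4"),
        ]
    )


@pytest.fixture
def nine_member_pedigree():
    """Three generations, nine members, two sib pairs of cousins."""
    return Pedigree(
        [
            Individual("1"),
            Individual("2"),
            Individual("5"),
            Individual("8"),
            Individual("3", "1", "2"),
            Individual("4", "1", "2"),
            Individual("6", "3", "5"),
            Individual("7", "3", "5"),
            Individual("9", "4", "8"),
        ]
    )


def gene_drop_marker(ped, freq, rng, alleles=("a", "r")):
    """Drop one multi-allelic marker through a pedigree; returns genotypes."""
    probs = [freq[a] for a in alleles]
    al = {}
    for f in ped.founders:
        al[f] = tuple(rng.choice(alleles, p=probs, size=2))
    for nf in ped.topological_nonfounders():
        ind = ped[nf]
        al[nf] = (
            al[ind.father][rng.integers(2)],
            al[ind.mother][rng.integers(2)],
        )
    return al
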