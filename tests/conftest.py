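import numpy as np
import pytest

import nrvat


@pytest.fixture(scope="session")
def default_ped():
    return nrvat.default_pedigree_set()


@pytest.fixture(scope="session")
def octet(default_ped):
    """Three-generation family: grandparents, two couples, two first cousins."""
    return default_ped.families[-1]


@pytest.fixture(scope="session")
def trio(default_ped):
    return default_ped.families[0]


def singleton_pedigree(n: int) -> nrvat.Pedigree:
    """n unrelated subjects, one per family (the unrelated-sample limit)."""
    return nrvat.Pedigree([
        nrvat.Family(f"S{i}", [nrvat.Individual("1")]) for i in range(n)
    ])


def parent_child_pedigree(n_pairs: int) -> nrvat.Pedigree:
    """n trio families; the (parent, child) entries carry Psi = 0.5."""
    fams = []
    for i in range(n_pairs):
        fams.append(nrvat.Family(f"D{i}", [
            nrvat.Individual("1", sex="male"),
            nrvat.Individual("2", sex="female"),
            nrvat.Individual("3", "1", "2"),
        ]))
    return nrvat.Pedigree(fams)
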