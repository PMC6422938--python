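import numpy as np
import pandas as pd
import pytest

from twinh2 import (Pedigree, compute_relatedness, eigendecompose,
                    make_twin_pedigree)


@pytest.fixture(scope="session")
def small_twin_structure():
    """10 MZ + 10 DZ pair families with relatedness and eigendecomposition."""
    ped = make_twin_pedigree(10, 10, phenotype_founders=False)
    rel = compute_relatedness(ped)
    return ped, rel, eigendecompose(rel)


@pytest.fixture(scope="session")
def quad_family_pedigree():
    """One fully phenotyped nuclear family: two founders and two DZ twins."""
    tab = pd.DataFrame({
        "id": ["fa", "mo", "t1", "t2"],
        "father": ["", "", "fa", "fa"],
        "mother": ["", "", "mo", "mo"],
        "sex": ["male", "female", "male", "female"],
        "mz_group": ["", "", "", ""],
        "family": ["f1"] * 4,
        "phenotyped": [True] * 4,
    })
    return Pedigree(tab)


@pytest.fixture(scope="session")
def mz_plus_sib_pedigree():
    """Five-person family: founder parents, an MZ twin pair, and a singleton
    full sibling of the twins."""
    tab = pd.DataFrame({
        "id": ["fa", "mo", "t1", "t2", "sib"],
        "father": ["", "", "fa", "fa", "fa"],
        "mother": ["", "", "mo", "mo", "mo"],
        "sex": ["male", "female", "male", "male", "female"],
        "mz_group": ["", "", "tw", "tw", ""],
        "family": ["f1"] * 5,
        "phenotyped": [True] * 5,
    })
    return Pedigree(tab)


@pytest.fixture(scope="session")
def three_generation_pedigree():
    """Grandparents, two parents (one married-in founder), grandchild, and an
    aunt — exercises the kinship recursion beyond one generation."""
    tab = pd.DataFrame({
        "id": ["gfa", "gmo", "pa", "aunt", "wife", "kid"],
        "father": ["", "", "gfa", "gfa", "", "pa"],
        "mother": ["", "", "gmo", "gmo", "", "wife"],
        "sex": ["male", "female", "male", "female", "female", "male"],
        "mz_group": [""] * 6,
        "family": ["f1"] * 6,
        "phenotyped": [True] * 6,
    })
    return Pedigree(tab)
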