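import numpy as np
import pytest

from bhlh_survey import catalog as cat_mod
from bhlh_survey.catalog import (
    load_family_catalog,
    mouse_like_family_counts,
    outgroup_motif,
    synthesize_reference_set,
)


@pytest.fixture(scope="session")
def catalog():
    return load_family_catalog()


@pytest.fixture(scope="session")
def rep_set(catalog):
    """Synthetic stand-in for the 45-family representative motif set."""
    return synthesize_reference_set(catalog, 1, seed=0)


@pytest.fixture(scope="session")
def mouse_set(catalog):
    """Synthetic stand-in for the 114-motif mouse reference set."""
    return synthesize_reference_set(
        catalog, mouse_like_family_counts(catalog), seed=0
    )


@pytest.fixture(scope="session")
def outgroup():
    return outgroup_motif()


@pytest.fixture(scope="session")
def profile(rep_set):
    return cat_mod.build_conserved_profile(rep_set)


@pytest.fixture(scope="session")
def scan_queries(rep_set, mouse_set):
    seen, out = set(), []
    for r in rep_set + mouse_set:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
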