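import numpy as np
import pytest

from crossgrm import (
    AUTOSOMAL,
    X,
    compute_line_frequencies,
    gametic_moments,
    line_composition,
    make_fixture,
    two_inbred_lines,
)
from crossgrm.fixtures import FixtureSpec, LineSpec


def two_line_spec(seed=0, **kwargs):
    """Two polymorphic lines with uniform(0,1) frequency spectra."""
    defaults = dict(
        lines=[
            LineSpec("A", 2, 2, ("uniform",)),
            LineSpec("B", 2, 2, ("uniform",)),
        ],
        n_autosomal=60,
        n_x=30,
        template="ail",
        generations=3,
        litter_size=4,
        seed=seed,
    )
    defaults.update(kwargs)
    return FixtureSpec(**defaults)


@pytest.fixture(scope="session")
def inbred_cross():
    """4 line-A males × 4 line-B females, lines fixed for opposite alleles."""
    ped, g, truth = make_fixture(
        two_inbred_lines(n_autosomal=12, n_x=6, template="ail", generations=3,
                         litter_size=4)
    )
    return ped, g, truth


@pytest.fixture(scope="session")
def inbred_moments(inbred_cross):
    ped, g, truth = inbred_cross
    freqs = compute_line_frequencies(g)
    return freqs, gametic_moments(freqs, AUTOSOMAL), gametic_moments(freqs, X)


@pytest.fixture(scope="session")
def polymorphic_cross():
    """Two-line AIL with within-line polymorphism (all matrices invertible)."""
    ped, g, truth = make_fixture(two_line_spec(seed=11, generations=4))
    freqs = compute_line_frequencies(g)
    return ped, g, freqs


@pytest.fixture(scope="session")
def polymorphic_objects(polymorphic_cross):
    ped, g, freqs = polymorphic_cross
    lc = line_composition(ped)
    moms = {p: gametic_moments(freqs, p) for p in (AUTOSOMAL, X)}
    return ped, g, freqs, lc, moms
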