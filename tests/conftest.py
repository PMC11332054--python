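import numpy as np
import pytest

import mcmkit as mk


@pytest.fixture
def eq2_matrix():
    """Three-stage matrix: reproduce in stage 3, grow 1->2->3, persist in 3."""
    return mk.StageMatrix(
        [[0.0, 0.0, 2.0], [0.5, 0.0, 0.0], [0.0, 0.4, 0.8]],
        ("s1", "s2", "s3"),
        mk.default_roles(3),
    )


@pytest.fixture
def toy():
    return mk.two_species_toy(asymmetry=0.5, seed=0)


@pytest.fixture(scope="session")
def riparian():
    return mk.riparian_like(seed=0)


@pytest.fixture(scope="session")
def fish3():
    return mk.fish_like(n_species=3, seed=0)


def scalar_species(sid: str, survival_by_year: dict[str, float]) -> mk.SpeciesModel:
    """A one-stage species with survival-only dynamics."""
    return mk.SpeciesModel(
        sid,
        {
            yt: mk.StageMatrix([[s]], ("adult",), np.array([["P"]], dtype="<U1"))
            for yt, s in survival_by_year.items()
        },
        [1.0],
    )


@pytest.fixture
def disconnected_pair():
    """Two scalar species with NO coupling: perturbing A cannot reach B."""
    a = scalar_species("A", {"good": 0.9, "bad": 0.8})
    b = scalar_species("B", {"good": 0.9, "bad": 0.8})
    regime = mk.Regime.iid(("good", "bad"), (0.5, 0.5))
    return mk.CommunityModel([a, b], regime, dependency=None)
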