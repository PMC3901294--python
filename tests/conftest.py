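import numpy as np
import pytest

from fluxpdf.network_model import (
    ExchangePrior,
    MetabolicNetwork,
    Metabolite,
    Reaction,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_reaction_net():
    """Smallest valid instance: one internal metabolite A with x1 - x2 = 0."""
    return MetabolicNetwork(
        reactions=[Reaction("r1", 0.0, 1.0), Reaction("r2", 0.0, 1.0)],
        metabolites=[Metabolite("A")],
        stoichiometry=[("A", "r1", 1.0), ("A", "r2", -1.0)],
    )


@pytest.fixture
def mixed_prior_net():
    """Small instance exercising all three prior kinds."""
    return MetabolicNetwork(
        reactions=[
            Reaction("r1", 0.0, 1.0),
            Reaction("r2", -0.5, 1.5),
            Reaction("r3", 0.0, 2.0),
        ],
        metabolites=[
            Metabolite("A"),
            Metabolite("B", ExchangePrior("uniform", lb=-0.3, ub=0.3)),
            Metabolite("C", ExchangePrior("fixed", z0=0.25)),
        ],
        stoichiometry=[
            ("A", "r1", 1.0),
            ("A", "r2", -1.0),
            ("B", "r2", 1.0),
            ("B", "r3", -0.5),
            ("C", "r3", 1.0),
        ],
    )
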