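import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from fluxcord.model import (
    FluxRatioConstraint,
    Metabolite,
    Reaction,
    StoichiometricModel,
)


def chain_model(uptake: float = 10.0) -> StoichiometricModel:
    """A -> B -> biomass linear chain, uptake-limited."""
    return StoichiometricModel(
        id="chain",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0, uptake, exchange=True),
            Reaction("conv", {"A": -1.0, "B": 1.0}, 0, 1000),
            Reaction("biomass", {"B": -1.0}, 0, 1000),
        ],
        objective="biomass",
    )


def parallel_model() -> StoichiometricModel:
    """Two equivalent branches from A to B; total flux pinned by uptake."""
    return StoichiometricModel(
        id="parallel",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0, 10, exchange=True),
            Reaction("branch1", {"A": -1.0, "B": 1.0}, 0, 1000),
            Reaction("branch2", {"A": -1.0, "B": 1.0}, 0, 1000),
            Reaction("biomass", {"B": -1.0}, 0, 1000),
        ],
        objective="biomass",
    )


def branched_model(ratio: float | None = None) -> StoichiometricModel:
    """Uptake splits into a branch and a bypass re-merging at biomass;
    optionally a flux ratio pins branch/uptake."""
    ratios = (
        [FluxRatioConstraint("branch", "uptake", ratio)]
        if ratio is not None
        else []
    )
    return StoichiometricModel(
        id="branched",
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction("uptake", {"A": 1.0}, 0, 10, exchange=True),
            Reaction("branch", {"A": -1.0, "B": 1.0}, 0, 1000),
            Reaction("bypass", {"A": -1.0, "C": 1.0}, 0, 1000),
            Reaction("merge", {"B": -1.0, "C": 1.0}, 0, 1000),
            Reaction("biomass", {"C": -1.0}, 0, 1000),
        ],
        objective="biomass",
        flux_ratios=ratios,
    )


@pytest.fixture
def chain():
    return chain_model()


@pytest.fixture
def parallel():
    return parallel_model()


@pytest.fixture(
    params=["chain", "parallel", "branched", "branched_pinned"],
)
def tiny_model(request):
    """Every shipped toy model small enough for vertex enumeration."""
    return {
        "chain": chain_model,
        "parallel": parallel_model,
        "branched": branched_model,
        "branched_pinned": lambda: branched_model(ratio=0.5),
    }[request.param]()
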