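import pytest

from hubsig.interactome import Interactome, PathwayMap
from hubsig.synthcohort import (
    default_design,
    generate_cohort,
    generate_interactome,
    generate_pathways,
)


@pytest.fixture(scope="session")
def interactome500():
    """Mid-sized scale-free interactome shared across modules."""
    return generate_interactome(500, 2, seed=11)


@pytest.fixture(scope="session")
def pathways8(interactome500):
    return generate_pathways(
        interactome500, genes_per_pathway=50, overlap_fraction=0.2, seed=13
    )


@pytest.fixture(scope="session")
def cohort(interactome500, pathways8):
    """Default-design synthetic cohort: (profiles, ground truth)."""
    design = default_design(interactome500, pathways8, seed=17)
    return generate_cohort(design, interactome500)


@pytest.fixture
def toy_interactome():
    """Hand-built graph: a 4-clique, a chain hanging off it, and a hub."""
    edges = [
        ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"),
        ("D", "E"), ("E", "F"), ("F", "G"),
        ("HUB", "A"), ("HUB", "B"), ("HUB", "E"), ("HUB", "G"), ("HUB", "X"),
        ("X", "Y"),
    ]
    return Interactome(edges)


@pytest.fixture
def toy_pathways():
    return PathwayMap({"P1": {"A", "B", "C"}, "P2": {"C", "D", "HUB"}})
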