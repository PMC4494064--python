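import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from paleozyme import synthetic_data
from paleozyme.phylosignal import poisson_model
from paleozyme.treecore import parse_newick


@pytest.fixture(scope="session")
def species3():
    """Three-taxon species tree ((A,B),C)."""
    return parse_newick("((A,B),C);")


@pytest.fixture(scope="session")
def species4():
    """Balanced four-taxon species tree."""
    return parse_newick("((A,B),(C,D));")


@pytest.fixture(scope="session")
def dated_tree10():
    """Ten-taxon dated Yule tree, root at 800 Ma."""
    return synthetic_data.sim_species_tree(10, 1.0, 800.0, seed=11)


@pytest.fixture(scope="session")
def dated_tree12():
    """Twelve-taxon dated Yule tree, root at 887 Ma."""
    return synthetic_data.sim_species_tree(12, 1.0, 887.0, seed=7)


@pytest.fixture(scope="session")
def aa_model():
    """Poisson 20-state model, rate homogeneity."""
    return poisson_model(20)


@pytest.fixture(scope="session")
def aa_model_gamma():
    """Poisson 20-state model with 4 discrete gamma categories."""
    return poisson_model(20, alpha=0.8, n_categories=4)
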