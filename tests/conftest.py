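import numpy as np
import pytest

from ncrphylo.tree import parse_gene_tree, parse_species_tree
from ncrphylo.synthetic import (
    SimulationConfig,
    default_species_tree,
    gainloss_species_tree,
)


@pytest.fixture(scope="session")
def species5():
    """Fixed 5-taxon binary species tree used by the reconciliation oracles."""
    tree = parse_species_tree("((A:1,B:1)AB:1,((C:1,D:1)CD:1,E:2)CDE:1)root;")
    tree.prepare()
    return tree


@pytest.fixture(scope="session")
def species2():
    tree = parse_species_tree("(A:1,B:1)root;")
    tree.prepare()
    return tree


@pytest.fixture(scope="session")
def species12():
    return default_species_tree()


@pytest.fixture(scope="session")
def species6():
    return gainloss_species_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160315)


@pytest.fixture()
def config():
    return SimulationConfig(seed=7)


def gt(newick: str):
    """Parse a gene tree whose leaf names encode species as gene_SPECIES."""
    tree = parse_gene_tree(newick)
    for leaf in tree.leaves():
        if leaf.species_id is None:
            leaf.species_id = leaf.gene_id.rsplit("_", 1)[-1]
    return tree


@pytest.fixture(scope="session")
def make_gene_tree():
    return gt
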