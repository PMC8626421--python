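import numpy as np
import pytest

from phyloconcord import (
    GeneTreeSet,
    SimulationConfig,
    as_species_tree_cu,
    parse_newick,
    simulate_gene_trees,
)
from phyloconcord.synthetic import gen_species_tree


@pytest.fixture(scope="session")
def balanced5():
    """Ultrametric 5-taxon species tree with a 1-CU focal branch above {A,B}."""
    return parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")


@pytest.fixture(scope="session")
def msc_trees_t1(balanced5):
    """5,000 MSC gene trees from the balanced 5-taxon tree (session-cached)."""
    sp = as_species_tree_cu(balanced5)
    return simulate_gene_trees(sp, SimulationConfig(n_trees=5000, seed=1234))


@pytest.fixture(scope="session")
def synthetic_pair6():
    """A matched (coalescent, mutation) species-tree pair, theta = 0.1."""
    return gen_species_tree(6, (0.5, 2.0), 0.1, seed=77)


def random_tree_newick(seed: int, n_taxa: int = 6, supports: bool = False) -> str:
    """Deterministic random binary newick used by round-trip style tests."""
    from phyloconcord.synthetic import _random_topology
    from phyloconcord.tree import PhyloTree, write_newick

    rng = np.random.Generator(np.random.PCG64(seed))
    root = _random_topology([f"x{i}" for i in range(n_taxa)], rng)
    for node in root.postorder():
        if node.parent is not None:
            node.length = float(np.round(rng.uniform(0.01, 2.0), 6))
            if supports and not node.is_leaf:
                node.support = float(rng.integers(0, 101))
    return write_newick(PhyloTree(root))
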