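import random

import pytest

from plastevol.molevol import BranchTree
from plastevol.synthetic_data import SimConfig, simulate_plastome


@pytest.fixture(scope="session")
def small_plastome():
    """A quadripartite synthetic plastome at reduced gene scale (fast)."""
    rec, ledger = simulate_plastome(SimConfig(seed=11, gene_scale=0.25))
    return rec, ledger


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return BranchTree.from_newick(
        "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,((E:0.1,F:0.1):0.05,(G:0.1,H:0.1):0.05):0.05);"
    )


@pytest.fixture(scope="session")
def balanced_22_tree():
    """A fixed 22-taxon tree used by the comparative-statistics suites."""
    import dendropy

    rng = random.Random(7)
    taxa = [f"t{i:02d}" for i in range(22)]
    tns = dendropy.TaxonNamespace(taxa)
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
        num_extant_tips=len(taxa), rng=rng,
    )
    return BranchTree.from_dendropy(t)
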