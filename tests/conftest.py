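import numpy as np
import pytest

from recescan.phylo import PhyloTree, SubstitutionModel
from recescan.simulate import default_tree


@pytest.fixture(scope="session")
def primate_tree() -> PhyloTree:
    return default_tree()


@pytest.fixture(scope="session")
def hky() -> SubstitutionModel:
    return SubstitutionModel.hky85(np.array([0.3, 0.2, 0.2, 0.3]), kappa=3.0)


@pytest.fixture(scope="session")
def jc() -> SubstitutionModel:
    return SubstitutionModel.jc69()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_tree(n_leaves, rng, min_len=0.01, max_len=0.3) -> PhyloTree:
    """Random rooted binary tree by sequential leaf attachment."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = []
    for i in range(2):
        nd = tree.seed_node.new_child(edge_length=float(rng.uniform(min_len, max_len)))
        nd.taxon = taxa[i]
        leaves.append(nd)
    for i in range(2, n_leaves):
        host = leaves[rng.integers(len(leaves))]
        host_len = host.edge.length
        parent = host.parent_node
        parent.remove_child(host)
        mid = parent.new_child(edge_length=host_len / 2)
        host.edge.length = host_len / 2
        mid.add_child(host)
        nd = mid.new_child(edge_length=float(rng.uniform(min_len, max_len)))
        nd.taxon = taxa[i]
        leaves.append(nd)
    newick = tree.as_string(schema="newick").strip()
    if not newick.endswith(";"):
        newick += ";"
    return PhyloTree.from_newick(newick.lstrip("[&R] "))


def random_model(rng) -> SubstitutionModel:
    pi = rng.dirichlet(np.ones(4) * 5)
    rates = rng.uniform(0.5, 2.5, size=6)
    return SubstitutionModel.gtr(pi, rates)
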