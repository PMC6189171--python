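import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_binary_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random binary tree with strictly positive branch lengths (0.05-1.0)."""
    labels = [f"T{i}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(0.05, 1.0))
        b.edge.length = float(rng.uniform(0.05, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for nd in nodes:
        tree.seed_node.add_child(nd)
        nd.edge.length = float(rng.uniform(0.05, 1.0))
    tree.is_rooted = False
    return tree


def additive_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Patristic (additive) distance matrix of a tree plus its tip labels."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    idx = {lab: i for i, lab in enumerate(labels)}
    D = np.zeros((len(labels), len(labels)))
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1.label < t2.label:
                d = pdm.patristic_distance(t1, t2)
                D[idx[t1.label], idx[t2.label]] = D[idx[t2.label], idx[t1.label]] = d
    return D, labels
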