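import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_tree(labels, rng, min_bl=0.01, max_bl=1.0):
    """Random unrooted binary tree over labels with uniform branch lengths."""
    ns = dendropy.TaxonNamespace(list(labels))
    nodes = []
    for lab in labels:
        n = dendropy.Node()
        n.taxon = ns.get_taxon(lab)
        nodes.append(n)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        a, b = nodes[j], nodes[i]
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for child in nodes:
        center.add_child(child)
        child.edge.length = float(rng.uniform(min_bl, max_bl))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree):
    """Leaf-to-leaf path distances of a dendropy tree as (labels, matrix)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ns = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(ns[labels[i]], ns[labels[j]])
    return labels, m
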