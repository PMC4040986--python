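import dendropy
import numpy as np
import pytest

from darkbin import synth
from darkbin.consistency import TaxonomyMap


def random_binary_tree(labels, rng, bl_range=(0.05, 0.2)):
    """Random binary topology over the labels with uniform branch lengths."""
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(*bl_range))
        b.edge.length = float(rng.uniform(*bl_range))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = False
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def taxonomy60():
    """3 domains / 6 phyla / 12 classes, 5 genomes per class."""
    return synth.make_taxonomy(60, n_domains=3, n_phyla=6, n_classes=12)


@pytest.fixture
def small_taxonomy():
    """12 genomes in 2 domains / 2 phyla / 2 classes (6 per clade)."""
    return synth.make_taxonomy(12, n_domains=2, n_phyla=2, n_classes=2)
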