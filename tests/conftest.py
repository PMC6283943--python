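import numpy as np
import pytest

from palaeopsin import datasets
from palaeopsin.dated_trees import DatedNode, DatedTree, parse_dated_tree
from palaeopsin.reconciliation import TipMap


@pytest.fixture(scope="session")
def opsin_chain():
    """The bundled dated opsin duplication chain."""
    return datasets.ecdysozoan_gene_lineage_tree()


@pytest.fixture(scope="session")
def divergences():
    """The five focal divergence intervals along the arthropod stem."""
    return datasets.ecdysozoan_divergences()


@pytest.fixture(scope="session")
def species_tree():
    return datasets.ecdysozoan_species_tree()


@pytest.fixture(scope="session")
def gene_tree():
    return datasets.ecdysozoan_gene_tree()


@pytest.fixture(scope="session")
def tip_map():
    return datasets.ecdysozoan_tip_map()


@pytest.fixture(scope="session")
def presence():
    return datasets.ecdysozoan_presence()


def bare(newick: str) -> DatedTree:
    """Parse a topology-only tree."""
    return parse_dated_tree(newick, dialect="bare")


# ---------------------------------------------------------------------------
# random tree corpora for oracle-equivalence testing
# ---------------------------------------------------------------------------


def random_topology(rng: np.random.Generator, tip_labels) -> DatedTree:
    """Uniform-ish random rooted binary topology over the given tips."""
    nodes = [DatedNode(label=lab, age=0.0) for lab in tip_labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(DatedNode(children=[a, b]))
    return DatedTree(nodes[0])


def random_gene_species_pair(rng: np.random.Generator, max_tips: int = 7):
    """A random species tree, gene tree and tip map (gene tree ≤ max_tips)."""
    n_species = int(rng.integers(2, 6))
    species_labels = [f"S{i}" for i in range(n_species)]
    sp = random_topology(rng, species_labels)
    n_genes = int(rng.integers(2, max_tips + 1))
    homes = rng.integers(0, n_species, size=n_genes)
    gene_labels, pairs = [], []
    for k, h in enumerate(homes):
        lab = f"{species_labels[h]}_g{k}"
        gene_labels.append(lab)
        pairs.append((lab, species_labels[h], f"g{k}"))
    gt = random_topology(rng, gene_labels)
    return gt, sp, TipMap.from_pairs(pairs)
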