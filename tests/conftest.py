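import numpy as np
import pytest

from locusfilter.phyio import Alignment, parse_newick
from locusfilter.aln_stats import TaxonRoster


@pytest.fixture
def roster4():
    return TaxonRoster(("A", "B", "C", "D"))


@pytest.fixture
def roster10():
    return TaxonRoster(tuple(f"T{i}" for i in range(10)))


@pytest.fixture
def simple_aln():
    return Alignment("m1", "uce", {
        "A": "ACGTACGTACGT",
        "B": "ACGTACGTACGT",
        "C": "ACGTACGTTGCA",
        "D": "ACGTACGTTGCA",
    })


@pytest.fixture
def balanced_tree():
    return parse_newick("((A:1,B:1)95:1,(C:1,D:1)80:1);", "m1")


def random_alignment(rng: np.random.Generator, n_taxa=None, length=None,
                     alphabet="ACGTN-?", marker_id="rand") -> Alignment:
    n_taxa = n_taxa or int(rng.integers(2, 8))
    length = length or int(rng.integers(1, 60))
    chars = np.array(list(alphabet))
    rows = {
        f"t{i}": "".join(rng.choice(chars, size=length))
        for i in range(n_taxa)
    }
    return Alignment(marker_id, "unified", rows)


def random_topology_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary tree string built by sequential leaf attachment."""
    import io

    nodes = [f"L{i}" for i in range(n_leaves)]
    # combine randomly until one node remains
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        merged = f"({a}:1,{b}:1)"
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(merged)
    return nodes[0] + ";"
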