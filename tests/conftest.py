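import dendropy
import numpy as np
import pandas as pd
import pytest

from archflux.core_io import CircularGenome, GeneRecord, OrthologMatrix


def make_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string with internal labels as percent supports."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for node in tree:
        if node.is_leaf():
            node.support = None
        else:
            try:
                node.support = float(node.label) if node.label else None
            except (TypeError, ValueError):
                node.support = None
    return tree


@pytest.fixture
def quartet_tree() -> dendropy.Tree:
    return make_tree("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0):0.0;")


@pytest.fixture
def small_genome() -> CircularGenome:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return CircularGenome(id="g1", length=10_000, ori=0, ter=5_000, sequence=seq)


@pytest.fixture
def simple_matrix() -> OrthologMatrix:
    return OrthologMatrix(
        pd.DataFrame(
            {"A": [1, 1, 1], "B": [1, 1, 0], "C": [0, 1, 0], "D": [0, 1, 2]},
            index=["f1", "f2", "f3"],
        )
    )


def gene(gene_id, start, end, genome_id="g1", strand="+", category="", flags=()):
    return GeneRecord(gene_id, genome_id, start, end, strand, category,
                      set(flags))
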