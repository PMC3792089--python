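from __future__ import annotations

import numpy as np
import pytest

from hredetect.core import GenomeLayout, SignedSNP, Weights
from hredetect.io import read_tree_string


def make_layout(genome_id: str, *contig_specs: str) -> GenomeLayout:
    """Build a layout from compact contig strings like ``"a b -c"``.

    Letters map to loci (a=0, b=1, ...); a leading ``-`` means reverse
    orientation.
    """
    contigs = []
    for spec in contig_specs:
        contig = []
        for token in spec.split():
            orient = 1
            if token.startswith("-"):
                orient = -1
                token = token[1:]
            contig.append(SignedSNP(ord(token) - ord("a"), orient))
        contigs.append(contig)
    return GenomeLayout(genome_id, contigs)


def snps(spec: str) -> list[SignedSNP]:
    return make_layout("_", spec).contigs[0]


@pytest.fixture
def balanced4():
    """((A,B),(C,D)); 7 nodes, unit branch lengths."""
    return read_tree_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def default_weights():
    return Weights()


def random_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree topology with unit branch lengths."""
    from hredetect.tree import PhyloTree, _TmpNode

    nodes = [_TmpNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = _TmpNode()
        parent.children = [left, right]
        nodes.append(parent)
    nodes[0].length = 0.0
    return PhyloTree.from_tmp(nodes[0])
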