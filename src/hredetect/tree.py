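"""Rooted species trees and homoplasy-based rooting.

A tree over ``n`` genomes has ``2n - 1`` nodes.  Node numbering is
canonical and deterministic: leaves take ids ``0 .. n-1`` in traversal
(input) order, internal nodes take ids ``n .. 2n-2`` in post-order
completion order, so the root is always ``2n - 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import MISSING


@dataclass
class _TmpNode:
    """Scratch node used while assembling a tree before canonical numbering."""

    length: float = 1.0
    name: Optional[str] = None
    children: list["_TmpNode"] = field(default_factory=list)


class PhyloTree:
    """Rooted tree with parent pointers, branch lengths and leaf genome ids."""

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        lengths: Sequence[float],
        genome_ids: Sequence[Optional[str]],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = tuple(tuple(c) for c in children)
        self.lengths = np.asarray(lengths, dtype=float)
        self.genome_ids = list(genome_ids)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.n_nodes = len(self.parent)
        self.leaf_ids = [i for i in range(self.n_nodes) if not self.children[i]]
        self.n_leaves = len(self.leaf_ids)
        self.leaf_of_genome = {
            self.genome_ids[i]: i for i in self.leaf_ids if self.genome_ids[i] is not None
        }
        self._postorder: Optional[list[int]] = None
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_tmp(cls, root: _TmpNode) -> "PhyloTree":
        """Number a scratch tree canonically and freeze it."""
        leaves: list[_TmpNode] = []
        internals: list[_TmpNode] = []

        def walk(node: _TmpNode) -> None:
            if not node.children:
                leaves.append(node)
                return
            for ch in node.children:
                walk(ch)
            internals.append(node)

        walk(root)
        ids: dict[int, int] = {}
        for i, node in enumerate(leaves):
            ids[id(node)] = i
        for j, node in enumerate(internals):
            ids[id(node)] = len(leaves) + j

        n = len(leaves) + len(internals)
        parent = [-1] * n
        children: list[list[int]] = [[] for _ in range(n)]
        lengths = [0.0] * n
        genome_ids: list[Optional[str]] = [None] * n

        def fill(node: _TmpNode) -> None:
            i = ids[id(node)]
            lengths[i] = node.length
            genome_ids[i] = node.name if not node.children else None
            for ch in node.children:
                j = ids[id(ch)]
                parent[j] = i
                children[i].append(j)
                fill(ch)

        fill(root)
        return cls(parent, children, lengths, genome_ids)

    # -- basic queries -------------------------------------------------

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def postorder(self) -> list[int]:
        """Node ids with every child before its parent (computed once)."""
        if self._postorder is None:
            order: list[int] = []
            stack: list[tuple[int, bool]] = [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for ch in reversed(self.children[node]):
                        stack.append((ch, False))
            self._postorder = order
        return self._postorder

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def descendant_mask(self) -> np.ndarray:
        """Boolean (N, N) matrix: ``mask[i, j]`` iff j is i or a descendant of i."""
        n = self.n_nodes
        mask = np.eye(n, dtype=bool)
        for node in self.postorder():
            for ch in self.children[node]:
                mask[node] |= mask[ch]
        return mask

    def depths(self) -> np.ndarray:
        """Sum of branch lengths on the root-to-node path, per node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            if node != self.root:
                d[node] = d[self.parent[node]] + self.lengths[node]
        return d

    def validate(self) -> None:
        # parent pointers and children lists must describe the same tree
        for i in range(self.n_nodes):
            for ch in self.children[i]:
                if self.parent[ch] != i:
                    raise ValueError("inconsistent parent/children structure")
        if len(self.postorder()) != self.n_nodes:
            raise ValueError("tree is not connected")
        if np.any(self.lengths < 0):
            raise ValueError("negative branch length")

    # -- export --------------------------------------------------------

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if self.is_leaf(i):
                label = self.genome_ids[i] or f"n{i}"
            else:
                label = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if i == self.root:
                return label
            return f"{label}:{self.lengths[i]:.10g}"

        return rec(self.root) + ";"


# ---------------------------------------------------------------------------
# unit-cost parsimony change counts and homoplasy
# ---------------------------------------------------------------------------

_BIG = np.float64(1e18)


def min_changes(tree: PhyloTree, leaf_matrix: np.ndarray) -> np.ndarray:
    """Minimum number of state changes per locus, over all internal labelings.

    ``leaf_matrix`` is (n_leaves, L) of allele codes indexed by leaf node id;
    MISSING leaves are free (explainable by any state at zero cost).  Unit
    substitution cost; exact on arbitrary (also multifurcating) trees.
    """
    leaf_matrix = np.asarray(leaf_matrix)
    n_loci = leaf_matrix.shape[1]
    cost = np.zeros((tree.n_nodes, n_loci, 4))
    for node in tree.postorder():
        if tree.is_leaf(node):
            obs = leaf_matrix[node]
            c = np.zeros((n_loci, 4))
            observed = obs != MISSING
            c[observed] = _BIG
            c[observed, obs[observed]] = 0.0
            cost[node] = c
        else:
            acc = np.zeros((n_loci, 4))
            for ch in tree.children[node]:
                child = cost[ch]
                acc += np.minimum(child, child.min(axis=1, keepdims=True) + 1.0)
            cost[node] = acc
    best = cost[tree.root].min(axis=1)
    return np.rint(np.minimum(best, _BIG - 1)).astype(np.int64)


def homoplastic_loci(tree: PhyloTree, leaf_matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of loci needing more changes than (#observed alleles - 1)."""
    leaf_matrix = np.asarray(leaf_matrix)
    changes = min_changes(tree, leaf_matrix)
    n_alleles = np.array(
        [len(set(col[col != MISSING])) for col in leaf_matrix.T], dtype=np.int64
    )
    return changes > np.maximum(n_alleles - 1, 0)


def _unrooted_edges(tree: PhyloTree) -> tuple[dict[int, list[tuple[int, float]]], list[tuple[int, int]]]:
    """Undirected adjacency of the tree's unrooted topology.

    A degree-2 root (ordinary rooted binary tree) is suppressed so rooting
    candidates are genuine edges of the unrooted shape.  Edge order is
    deterministic: sorted by the original node-id pair.
    """
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(tree.n_nodes)}
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            adj[i].append((int(p), float(tree.lengths[i])))
            adj[int(p)].append((i, float(tree.lengths[i])))
    if len(tree.children[tree.root]) == 2:
        a, b = tree.children[tree.root]
        la, lb = float(tree.lengths[a]), float(tree.lengths[b])
        r = tree.root
        adj[a] = [(x, l) for x, l in adj[a] if x != r] + [(b, la + lb)]
        adj[b] = [(x, l) for x, l in adj[b] if x != r] + [(a, la + lb)]
        del adj[r]
    edges = sorted(
        {(min(u, v), max(u, v)) for u in adj for v, _ in adj[u]}
    )
    return adj, edges


def _root_on_edge(
    tree: PhyloTree,
    adj: Mapping[int, list[tuple[int, float]]],
    edge: tuple[int, int],
) -> PhyloTree:
    u, v = edge
    elen = next(l for x, l in adj[u] if x == v)

    def build(node: int, came_from: int, length: float) -> _TmpNode:
        tmp = _TmpNode(length=length, name=tree.genome_ids[node])
        for nxt, l in adj[node]:
            if nxt != came_from:
                tmp.children.append(build(nxt, node, l))
        return tmp

    root = _TmpNode(length=0.0)
    root.children = [build(u, v, elen / 2.0), build(v, u, elen / 2.0)]
    return PhyloTree.from_tmp(root)


def root_by_homoplasy(
    tree: PhyloTree, leaf_alleles: Mapping[str, np.ndarray]
) -> PhyloTree:
    """Root an (effectively unrooted) tree minimising homoplastic loci.

    Every edge of the unrooted topology is tried as a root position; the
    rooting with the fewest homoplastic loci wins, ties going to the first
    edge in the deterministic edge order.
    """
    if tree.n_leaves < 3:
        raise ValueError("rooting requires at least 3 leaves")
    adj, edges = _unrooted_edges(tree)
    best: Optional[tuple[int, int, PhyloTree]] = None
    for idx, edge in enumerate(edges):
        cand = _root_on_edge(tree, adj, edge)
        mat = np.stack(
            [np.asarray(leaf_alleles[cand.genome_ids[i]]) for i in cand.leaf_ids]
        )
        score = int(homoplastic_loci(cand, mat).sum())
        if best is None or score < best[0]:
            best = (score, idx, cand)
    assert best is not None
    return best[2]
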