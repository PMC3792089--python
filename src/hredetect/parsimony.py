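"""Weighted small parsimony (Sankoff) for ancestral allele reconstruction.

Each SNP column is treated independently: a state change on an edge into
an internal node costs ``w_m``, into a leaf ``w_e``.  Leaf states are the
observations; MISSING leaves are free (zero cost for every state), so
missingness can neither create nor forbid changes.  Columns of a block
are solved together (vectorised), which is purely an implementation
detail — the coupling of adjacent SNPs happens later, in the
recombination dynamic program, not here.
"""

from __future__ import annotations

import numpy as np

from .core import MISSING, Weights
from .tree import PhyloTree

_INF = np.float64(1e18)


def ancestral_states(
    tree: PhyloTree, leaf_matrix: np.ndarray, weights: Weights
) -> tuple[np.ndarray, np.ndarray]:
    """Infer internal alleles for every column of a block.

    Parameters
    ----------
    leaf_matrix : (n_leaves, m) allele codes indexed by leaf node id.

    Returns
    -------
    states : (n_nodes, m) matrix; leaf rows are the observations (MISSING
        preserved), internal rows the minimum-weight assignment.
    col_weight : (m,) minimal mutation+error weight per column.

    Tie-breaking in the backtrack prefers the parent's chosen state (the
    assignment reporting fewest events), then the alphabetically first
    base; the root breaks ties alphabetically.  All-MISSING columns get
    state 'A' everywhere and weight 0.
    """
    leaf_matrix = np.asarray(leaf_matrix)
    n_leaves, m = leaf_matrix.shape
    n = tree.n_nodes
    cost = np.zeros((n, m, 4))
    for node in tree.postorder():
        if tree.is_leaf(node):
            obs = leaf_matrix[node]
            c = np.zeros((m, 4))
            observed = obs != MISSING
            c[observed] = _INF
            c[observed, obs[observed]] = 0.0
            cost[node] = c
        else:
            acc = np.zeros((m, 4))
            for ch in tree.children[node]:
                w = weights.w_e if tree.is_leaf(ch) else weights.w_m
                child = cost[ch]
                acc += np.minimum(child, child.min(axis=1, keepdims=True) + w)
            cost[node] = acc

    states = np.full((n, m), MISSING, dtype=np.int64)
    states[:n_leaves] = leaf_matrix
    cols = np.arange(m)
    root = tree.root
    states[root] = np.argmin(cost[root], axis=1)
    col_weight = cost[root].min(axis=1)
    for node in tree.preorder():
        if tree.is_leaf(node):
            continue
        sp = states[node]
        for ch in tree.children[node]:
            if tree.is_leaf(ch):
                continue
            w = weights.w_m
            vals = cost[ch] + w
            vals[cols, sp] -= w
            pick = np.argmin(vals, axis=1)
            stay = vals[cols, sp] <= vals[cols, pick]
            pick[stay] = sp[stay]
            states[ch] = pick
    return states, col_weight


def infer_internal_alleles(
    tree: PhyloTree, leaf_column: np.ndarray, weights: Weights
) -> tuple[np.ndarray, float]:
    """Single-column convenience wrapper around :func:`ancestral_states`."""
    leaf_column = np.asarray(leaf_column).reshape(-1, 1)
    states, col_weight = ancestral_states(tree, leaf_column, weights)
    return states[:, 0], float(col_weight[0])
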