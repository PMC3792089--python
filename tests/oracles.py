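"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive (enumeration, recursion) and shares
no code with the implementation under test.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from hredetect.core import MISSING, GenomeLayout, SignedSNP
from hredetect.tree import PhyloTree


# ---------------------------------------------------------------------------
# block agreement
# ---------------------------------------------------------------------------


def oracle_agrees(layout: GenomeLayout, block) -> bool:
    """Enumerate all contig orders/orientations and duplicate-skip choices."""
    present = layout.present_loci
    dups = layout.duplicated_loci
    S = tuple(s for s in block.snps if s.locus in present)
    if not S:
        return True
    RC = tuple(s.reverse() for s in reversed(S))
    n = len(layout.contigs)
    for perm in permutations(range(n)):
        for mask in product((1, -1), repeat=n):
            T = []
            for ci, o in zip(perm, mask):
                contig = layout.contigs[ci]
                T.extend(contig if o > 0 else [s.reverse() for s in reversed(contig)])
            T = tuple(T)
            for target in (S, RC):
                if _subseq_match(T, target, frozenset(dups)):
                    return True
    return False


def _subseq_match(T, target, dups) -> bool:
    @lru_cache(maxsize=None)
    def go(t: int, s: int) -> bool:
        if s == len(target):
            return True
        if t == len(T):
            return False
        if T[t] == target[s] and go(t + 1, s + 1):
            return True
        if T[t].locus in dups and go(t + 1, s):
            return True
        return False

    return any(T[t0] == target[0] and go(t0, 0) for t0 in range(len(T)))


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------


def oracle_parsimony(tree: PhyloTree, leaf_column, weights) -> float:
    """Minimum mutation+error weight by enumerating all internal states."""
    internals = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    best = float("inf")
    for assign in product(range(4), repeat=len(internals)):
        state = dict(zip(internals, assign))
        cost = 0.0
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p < 0:
                continue
            if tree.is_leaf(i):
                obs = leaf_column[i]
                if obs != MISSING and obs != state[p]:
                    cost += weights.w_e
            elif state[i] != state[p]:
                cost += weights.w_m
        best = min(best, cost)
    return best


def oracle_fitch(tree: PhyloTree, leaf_column) -> int:
    """Unit-cost minimum change count by state enumeration."""

    class _W:
        w_m = 1.0
        w_e = 1.0

    return int(oracle_parsimony(tree, leaf_column, _W))


# ---------------------------------------------------------------------------
# the per-node source dynamic program
# ---------------------------------------------------------------------------


def _descendants(tree: PhyloTree, node: int) -> set[int]:
    out = set()
    stack = [node]
    while stack:
        x = stack.pop()
        out.add(x)
        stack.extend(tree.children[x])
    return out


def oracle_assign_weight(states, tree: PhyloTree, weights, outgroup: bool = True) -> float:
    """Exhaustive minimum over all per-node source-state sequences."""

    def mismatch(a, b, j) -> bool:
        return states[a][j] != MISSING and states[b][j] != MISSING and states[a][j] != states[b][j]

    m = len(states[0])
    total = 0.0
    for dest in range(tree.n_nodes):
        if dest == tree.root:
            continue
        parent = int(tree.parent[dest])
        w_edge = weights.w_e if tree.is_leaf(dest) else weights.w_m
        sources = sorted(set(range(tree.n_nodes)) - _descendants(tree, dest))
        space = ["P"] + sources + (["O"] if outgroup else [])
        best = float("inf")
        for seq in product(space, repeat=m):
            cost = 0.0
            prev = None
            for j, st in enumerate(seq):
                if st == "P":
                    if mismatch(dest, parent, j):
                        cost += w_edge
                elif st == "O":
                    cost += weights.w_t if prev == "O" else weights.w_o
                else:
                    if prev != st:
                        cost += weights.w_x
                    if mismatch(dest, st, j):
                        cost += w_edge
                prev = st
            best = min(best, cost)
        total += best
    return total
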