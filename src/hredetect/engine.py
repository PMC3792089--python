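"""Minimum-weight assignment of mutations, errors and recombination events.

For every non-root node, independently, a dynamic program scans the SNPs
of a block and decides per SNP whether the allele is inherited from the
parent (mismatches cost ``w_m`` on internal edges, ``w_e`` on leaf
edges), from an in-tree donor (any node that is not the destination or
one of its descendants; opening such a segment costs ``w_x``, charged
once at the start, and mismatches against the donor are still allowed at
mutation/error cost), or from an out-group donor (affine cost: ``w_o``
to open, ``w_t`` per extended SNP, matching any allele).  MISSING
alleles on either side never cost anything.

Ties are resolved lexicographically: minimise total weight first, then
the number of emitted events (one recombination beats three equal-weight
errors), then the recombined span (segments are reported over the
minimal SNP range that achieves the optimum, not padded with matching
SNPs).  Any remaining tie prefers the out-group state, then in-tree
donors by ascending node id, then parent inheritance.  The secondary
criteria are implemented as epsilon penalties several orders of
magnitude below any meaningful weight difference.
"""

from __future__ import annotations

import numpy as np

from .core import MISSING, OUTGROUP, EventCall, Weights
from .tree import PhyloTree

_INF = np.float64(1e18)
#: secondary tie-break penalties (events, then covered SNPs); must stay far
#: below any real weight difference and far apart from each other
_EPS_EVENT = 1e-7
_EPS_SPAN = 1e-10


def eligible_sources(tree: PhyloTree, dest: int) -> set[int]:
    """Donor candidates for ``dest``: every node that is neither ``dest``
    nor a proper descendant of it.  The root as destination has no parent
    edge and therefore no donors."""
    if dest == tree.root:
        return set()
    mask = tree.descendant_mask()[dest]
    return {k for k in range(tree.n_nodes) if not mask[k]}


def assign_events(
    states: np.ndarray,
    tree: PhyloTree,
    weights: Weights,
    block_id: int = 0,
    outgroup: bool = True,
) -> tuple[list[EventCall], float]:
    """Run the per-node source DP over a block and emit event calls.

    ``states`` is the (n_nodes, m) allele matrix: observed leaf rows,
    parsimony-inferred internal rows.  Returns the events plus the DP
    total weight, which equals the summed weights of the emitted events.
    """
    states = np.asarray(states)
    if states.shape[0] != tree.n_nodes:
        raise ValueError(
            f"allele matrix has {states.shape[0]} rows for a "
            f"{tree.n_nodes}-node tree"
        )
    n, m = states.shape
    if m < 1:
        raise ValueError("empty block")
    w_o = weights.w_o if outgroup else _INF

    valid = states != MISSING
    # mismatch[a, b, j]: alleles of nodes a and b differ at SNP j, both observed
    mismatch = (states[:, None, :] != states[None, :, :]) & valid[:, None, :] & valid[None, :, :]

    dests = np.array([i for i in range(n) if i != tree.root])
    edge_w = np.where([tree.is_leaf(int(d)) for d in dests], weights.w_e, weights.w_m)

    desc = tree.descendant_mask()
    # state axis layout: [0]=OUTGROUP, [1..n]=in-tree donor k-1, [n+1]=PARENT
    # (the axis order is the final tie-breaking priority; np.argmin takes
    # the first minimum)
    S = n + 2
    # per-SNP emission costs, with the secondary tie-break penalties folded
    # in: every point event adds _EPS_EVENT, every recombined SNP _EPS_SPAN
    e_src = mismatch[dests][:, :, :] * (edge_w[:, None, None] + _EPS_EVENT)  # (D, n, m)
    e_src = np.transpose(e_src, (0, 2, 1)) + _EPS_SPAN  # (D, m, n)
    ineligible = desc[dests]  # (D, n): dest itself and its descendants
    e_src[ineligible[:, None, :].repeat(m, axis=1)] = _INF
    parents = tree.parent[dests]
    e_par = mismatch[dests, parents, :] * (edge_w[:, None] + _EPS_EVENT)  # (D, m)

    open_x = weights.w_x + _EPS_EVENT   # opening a donor segment is one event
    open_o = w_o + _EPS_EVENT

    D = len(dests)
    V = np.empty((m, D, S))
    V[0, :, 0] = open_o + _EPS_SPAN
    V[0, :, 1 : n + 1] = open_x + e_src[:, 0, :]
    V[0, :, n + 1] = e_par[:, 0]
    for j in range(1, m):
        prev = V[j - 1]
        best = prev.min(axis=1)
        V[j, :, 0] = _EPS_SPAN + np.minimum(prev[:, 0] + weights.w_t, best + open_o)
        V[j, :, 1 : n + 1] = e_src[:, j, :] + np.minimum(
            prev[:, 1 : n + 1], (best + open_x)[:, None]
        )
        V[j, :, n + 1] = e_par[:, j] + best

    events: list[EventCall] = []
    for di, dest in enumerate(dests):
        dest = int(dest)
        path = np.empty(m, dtype=np.int64)
        state = int(np.argmin(V[m - 1, di]))
        path[m - 1] = state
        for j in range(m - 1, 0, -1):
            prev = V[j - 1, di]
            best_prev = prev.min()
            if state == n + 1:  # PARENT
                state = int(np.argmin(prev))
            elif state == 0:  # OUTGROUP
                if not prev[0] + weights.w_t <= best_prev + open_o:
                    state = int(np.argmin(prev))
            else:  # in-tree donor
                if not prev[state] <= best_prev + open_x:
                    state = int(np.argmin(prev))
            path[j - 1] = state
        events.extend(
            _emit(path, dest, int(parents[di]), states, mismatch, tree, block_id, n)
        )
    total = total_event_weight(events, weights)
    augmented = float(V[m - 1].min(axis=1).sum())
    assert abs(augmented - total) < 1e-3 * max(1.0, abs(total)) + 1e-3
    return events, total


def _emit(path, dest, parent, states, mismatch, tree, block_id, n) -> list[EventCall]:
    events: list[EventCall] = []
    m = len(path)
    point_kind = "error" if tree.is_leaf(dest) else "mutation"
    j = 0
    while j < m:
        state = path[j]
        j_end = j
        while j_end + 1 < m and path[j_end + 1] == state:
            j_end += 1
        if state == n + 1:  # parent inheritance: point events at mismatches
            for jj in range(j, j_end + 1):
                if mismatch[dest, parent, jj]:
                    events.append(
                        EventCall(point_kind, block_id, dest, jj, jj,
                                  allele_from=int(states[parent, jj]),
                                  allele_to=int(states[dest, jj]))
                    )
        elif state == 0:
            events.append(
                EventCall("outgroup_hre", block_id, dest, j, j_end, source=OUTGROUP)
            )
        else:
            k = state - 1
            events.append(EventCall("hre", block_id, dest, j, j_end, source=k))
            for jj in range(j, j_end + 1):
                if mismatch[dest, k, jj]:
                    events.append(
                        EventCall(point_kind, block_id, dest, jj, jj,
                                  allele_from=int(states[k, jj]),
                                  allele_to=int(states[dest, jj]))
                    )
        j = j_end + 1
    return events


def total_event_weight(events: list[EventCall], weights: Weights) -> float:
    """Recompute the DP objective from the emitted event list alone."""
    return sum(ev.weight(weights) for ev in events)


# ---------------------------------------------------------------------------
# origin tracing
# ---------------------------------------------------------------------------

_TERMINAL = -2


def trace_origins(
    events: list[EventCall], tree: PhyloTree, m: int, block_id: int = 0
) -> list[EventCall]:
    """Trace each (node, SNP) allele to its origin and flag inheritance cycles.

    Inside a recombination segment the origin is the donor's same SNP,
    otherwise the parent's.  Chains reaching the root (or an out-group
    segment) terminate; chains that fall into a cycle — two nodes
    predicted to inherit the same segment from each other, or longer
    loops — are evidence of an out-group event and are emitted as one
    ``outgroup_evidence`` call per cycle and contiguous SNP range.
    """
    n = tree.n_nodes
    origin = np.empty((n, m), dtype=np.int64)
    origin[:] = tree.parent[:, None]
    origin[tree.root, :] = _TERMINAL
    for ev in events:
        if ev.block_id != block_id:
            continue
        if ev.kind == "hre":
            origin[ev.dest_node, ev.j_start : ev.j_end + 1] = ev.source
        elif ev.kind == "outgroup_hre":
            origin[ev.dest_node, ev.j_start : ev.j_end + 1] = _TERMINAL

    cycles_at: dict[tuple[int, ...], list[int]] = {}
    for j in range(m):
        color = np.zeros(n, dtype=np.int8)  # 0 new, 1 on current chain, 2 done
        for start in range(n):
            if color[start]:
                continue
            chain = []
            node = start
            while node != _TERMINAL and color[node] == 0:
                color[node] = 1
                chain.append(node)
                node = int(origin[node, j])
            if node != _TERMINAL and color[node] == 1:
                cycle = chain[chain.index(node):]
                cycles_at.setdefault(tuple(sorted(cycle)), []).append(j)
            for c in chain:
                color[c] = 2

    evidence: list[EventCall] = []
    for nodes, js in sorted(cycles_at.items()):
        run_start = js[0]
        prev = js[0]
        for j in js[1:] + [None]:
            if j is None or j != prev + 1:
                evidence.append(
                    EventCall("outgroup_evidence", block_id, min(nodes),
                              run_start, prev, source=OUTGROUP,
                              cycle_nodes=tuple(nodes))
                )
                if j is not None:
                    run_start = j
            prev = j if j is not None else prev
    return evidence
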