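"""Branching-process simulator with mutations, recombination and noise.

Trees come from a random-branching (Yule-style) process: a single event
stream with exponential waiting times splits a uniformly chosen lineage
until the next split would create one strain too many; leaves are then
extended to that stop time, so every tree is ultrametric.  Branch
lengths are rescaled so the mean branch length is exactly
``avg_branch_length``, which makes the nominal branching rate a
scale-free knob.

Mutations arrive per edge as a Poisson process with rate
``mutation_rate * n_snps`` per unit branch length; recombination events
arrive per *ordered pair* of contemporaneous edges at ``hre_rate`` over
the shared time interval, copying the donor lineage's current alleles
over a uniformly chosen collinear segment.  Sequencing errors and
missing loci are added independently per leaf per SNP.  Event streams
are drawn as Poisson counts with uniform order-statistics times,
distributionally identical to sequential exponential waiting times.

Ground truth records every event; nullification flags mark events that
can leave no same-branch evidence (overwritten mutations, donor/recipient
segments differing at <=1 SNP, fully overwritten recombination events).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import MISSING, GenomeLayout, SignedSNP
from .io import SnpData
from .tree import PhyloTree, _TmpNode


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    Defaults are the baseline benchmark conditions: 40 strains, 50 SNPs,
    average branch length 20, recombination rate 3% and error rate 1%
    per unit branch length/SNP, missing rate 10%, and a baseline mutation
    rate of 3% per SNP per unit branch length (the rate shared by the
    default cells of the benchmark grid; the grid's mutation-rate row
    also explores 0.5-6%).  Inversions are off by default.
    """

    n_strains: int = 40
    branching_rate: float = 1.0
    avg_branch_length: float = 20.0
    n_snps: int = 50
    mutation_rate: float = 0.03
    hre_rate: float = 0.03
    error_rate: float = 0.01
    missing_rate: float = 0.10
    inversions_enabled: bool = False
    inversion_rate: float = 0.002
    p_symmetric: float = 0.8
    per_lineage_branching: bool = False
    #: draw recombination streams per ordered edge pair instead of per
    #: unordered pair with a random transfer direction (doubles intensity)
    ordered_pairs: bool = False
    #: segment sampling within a collinear region: "uniform_pairs" draws
    #: (position, length) jointly uniform over all segments that fit the
    #: region; "length_first" draws the length uniform on [1, region] and
    #: then a fitting start (longer segments over-weighted)
    hre_length_mode: str = "uniform_pairs"
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("branching_rate", "avg_branch_length", "mutation_rate",
                     "hre_rate", "error_rate", "missing_rate", "inversion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hre_length_mode not in ("uniform_pairs", "length_first"):
            raise ValueError(f"unknown hre_length_mode {self.hre_length_mode!r}")


@dataclass
class TrueEvent:
    """A simulated event; ``branch`` is the node id under the affected edge."""

    kind: str                      # mutation | hre | inversion | error | missing
    time: float
    branch: int
    locus_start: int = -1
    locus_end: int = -1
    source_branch: Optional[int] = None
    nullified: bool = False
    donor_mismatches: int = -1     # for hre: donor/recipient differences at event time


@dataclass
class SimResult:
    config: SimConfig
    tree: PhyloTree
    events: list[TrueEvent]
    node_alleles: np.ndarray       # (n_nodes, n_snps) truth, forward strand
    leaf_matrix: np.ndarray        # (n_leaves, n_snps) observed (errors+missing)
    leaf_orders: list[list[SignedSNP]]  # final SNP order per leaf node id

    def true_hres(self, include_nullified: bool = False) -> list[TrueEvent]:
        return [
            e for e in self.events
            if e.kind == "hre" and (include_nullified or not e.nullified)
        ]

    def to_snp_data(self) -> SnpData:
        """Package the observed leaves as a SNP matrix (one contig per leaf)."""
        layouts, alleles = [], {}
        for leaf in self.tree.leaf_ids:
            gid = self.tree.genome_ids[leaf]
            contig, positions = [], []
            allele_map = {}
            idx = 0
            for pos, snp in enumerate(self.leaf_orders[leaf], start=1):
                code = self.leaf_matrix[leaf, snp.locus]
                if code == MISSING:
                    continue
                contig.append(snp)
                positions.append(pos)
                # TSV alleles are as read on the recorded strand
                allele_map[(0, idx)] = code if snp.orient > 0 else 3 - code
                idx += 1
            layouts.append(GenomeLayout(gid, [contig], [positions]))
            alleles[gid] = allele_map
        return SnpData(list(range(self.config.n_snps)), layouts, alleles)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def simulate_tree(config: SimConfig, rng: np.random.Generator) -> PhyloTree:
    config.validate()
    n = config.n_strains
    rate = config.branching_rate

    @dataclass
    class _Lineage:
        tmp: _TmpNode
        birth: float

    t = 0.0
    root = _TmpNode(length=0.0)
    root.children = [_TmpNode(), _TmpNode()]
    active = [_Lineage(root.children[0], 0.0), _Lineage(root.children[1], 0.0)]
    while len(active) < n:
        scale = 1.0 / (rate * len(active)) if config.per_lineage_branching else 1.0 / rate
        t += rng.exponential(scale)
        i = int(rng.integers(len(active)))
        lin = active.pop(i)
        lin.tmp.length = t - lin.birth
        lin.tmp.children = [_TmpNode(), _TmpNode()]
        active.append(_Lineage(lin.tmp.children[0], t))
        active.append(_Lineage(lin.tmp.children[1], t))
    scale = 1.0 / (rate * len(active)) if config.per_lineage_branching else 1.0 / rate
    stop = t + rng.exponential(scale)
    for lin in active:
        lin.tmp.length = stop - lin.birth

    tree = PhyloTree.from_tmp(root)
    mean_len = float(np.delete(tree.lengths, tree.root).mean())
    tree.lengths = tree.lengths * (config.avg_branch_length / mean_len)
    tree.lengths[tree.root] = 0.0
    for i in tree.leaf_ids:
        tree.genome_ids[i] = f"g{i}"
    tree.leaf_of_genome = {tree.genome_ids[i]: i for i in tree.leaf_ids}
    return tree


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def simulate_events(
    tree: PhyloTree, config: SimConfig, rng: np.random.Generator
) -> list[TrueEvent]:
    """Draw mutation and recombination events on the tree's edges.

    Recombination locus ranges are assigned here when no inversions are
    simulated (the whole genome is one collinear region); with inversions
    they are chosen during realisation, when the lineages' current SNP
    orders are known.
    """
    depths = tree.depths()
    edges = np.array([i for i in range(tree.n_nodes) if i != tree.root])
    a = depths[tree.parent[edges]]
    b = depths[edges]
    events: list[TrueEvent] = []

    mu = config.mutation_rate * config.n_snps * (b - a)
    for ei, count in enumerate(rng.poisson(mu)):
        branch = int(edges[ei])
        for _ in range(count):
            t = float(rng.uniform(a[ei], b[ei]))
            locus = int(rng.integers(config.n_snps))
            events.append(TrueEvent("mutation", t, branch, locus, locus))

    lo = np.maximum(a[:, None], a[None, :])
    hi = np.minimum(b[:, None], b[None, :])
    overlap = np.clip(hi - lo, 0.0, None)
    np.fill_diagonal(overlap, 0.0)
    if not config.ordered_pairs:
        overlap = np.triu(overlap)  # one stream per unordered pair
    counts = rng.poisson(config.hre_rate * overlap)
    for si, di in zip(*np.nonzero(counts)):
        for _ in range(counts[si, di]):
            t = float(rng.uniform(lo[si, di], hi[si, di]))
            s, d = (si, di) if config.ordered_pairs or rng.integers(2) else (di, si)
            ev = TrueEvent("hre", t, int(edges[d]), source_branch=int(edges[s]))
            if not config.inversions_enabled:
                start, length = _sample_segment(config, config.n_snps, rng)
                ev.locus_start, ev.locus_end = start, start + length - 1
            events.append(ev)

    if config.inversions_enabled:
        events.extend(simulate_inversions(tree, config, rng))

    events.sort(key=lambda e: e.time)
    return events


def simulate_inversions(
    tree: PhyloTree, config: SimConfig, rng: np.random.Generator
) -> list[TrueEvent]:
    """Symmetric-leaning inversions on the circular SNP order.

    Each edge gets a Poisson number of inversions proportional to its
    length; an inversion's centre sits at the replication origin (index
    0 on the SNP circle) with probability ``p_symmetric``, else uniform,
    and its half-width is uniform.  The event's locus fields record the
    window as (start on the circle, length) at application time.
    """
    depths = tree.depths()
    events: list[TrueEvent] = []
    n = config.n_snps
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        t0, t1 = depths[tree.parent[i]], depths[i]
        for _ in range(rng.poisson(config.inversion_rate * (t1 - t0))):
            t = float(rng.uniform(t0, t1))
            center = 0 if rng.uniform() < config.p_symmetric else int(rng.integers(n))
            half = int(rng.integers(1, max(n // 2, 1) + 1))
            length = min(2 * half, n)
            start = (center - half) % n
            events.append(TrueEvent("inversion", t, i, start, length))
    return events


def _sample_segment(config: SimConfig, region: int, rng: np.random.Generator) -> tuple[int, int]:
    """Draw a (start, length) segment uniformly within a region of ``region``
    contiguous SNPs, per ``config.hre_length_mode``."""
    if config.hre_length_mode == "length_first":
        length = int(rng.integers(1, region + 1))
        start = int(rng.integers(0, region - length + 1))
        return start, length
    while True:  # joint-uniform over fitting segments, by rejection
        start = int(rng.integers(0, region))
        length = int(rng.integers(1, region + 1))
        if start + length <= region:
            return start, length


def apply_inversion(order: list[SignedSNP], start: int, length: int) -> list[SignedSNP]:
    """Signed reversal of a (possibly wrapping) window on the SNP circle."""
    n = len(order)
    idx = [(start + k) % n for k in range(length)]
    segment = [order[i].reverse() for i in reversed(idx)]
    out = list(order)
    for i, s in zip(idx, segment):
        out[i] = s
    return out


# ---------------------------------------------------------------------------
# realisation
# ---------------------------------------------------------------------------


def _collinear_intervals(
    src: list[SignedSNP], dst: list[SignedSNP]
) -> list[tuple[int, int]]:
    """Maximal runs of ``src`` order that are contiguous (same relative
    orientation) in ``dst``; returned as (start index in src, length)."""
    pos = {s.locus: (i, s.orient) for i, s in enumerate(dst)}
    n = len(src)
    runs: list[tuple[int, int]] = []
    start = 0
    while start < n:
        end = start
        while end + 1 < n:
            i1, o1 = pos[src[end].locus]
            i2, o2 = pos[src[end + 1].locus]
            rel1 = o1 * src[end].orient
            rel2 = o2 * src[end + 1].orient
            if rel1 == rel2 and i2 - i1 == rel1 and abs(i2 - i1) == 1:
                end += 1
            else:
                break
        runs.append((start, end - start + 1))
        start = end + 1
    return runs


def realize_alleles(
    tree: PhyloTree,
    events: list[TrueEvent],
    config: SimConfig,
    rng: np.random.Generator,
) -> SimResult:
    """Propagate root alleles down the tree applying events in time order.

    Returns the full ground truth plus the observed (error- and
    missing-perturbed) leaf matrix; recombination events get their
    donor/recipient mismatch counts recorded for nullification flagging.
    """
    n = config.n_snps
    depths = tree.depths()
    root_alleles = rng.integers(0, 4, size=n)
    alleles: dict[int, np.ndarray] = {}
    orders: dict[int, list[SignedSNP]] = {}
    base_order = [SignedSNP(l, 1) for l in range(n)]

    truth = np.zeros((tree.n_nodes, n), dtype=np.int64)
    truth[tree.root] = root_alleles
    for ch in tree.children[tree.root]:
        alleles[ch] = root_alleles.copy()
        orders[ch] = list(base_order)

    # interleave branching moments with the event stream
    branchings = sorted(
        (depths[i], i) for i in range(tree.n_nodes)
        if not tree.is_leaf(i) and i != tree.root
    )
    bi = 0
    for ev in events:
        while bi < len(branchings) and branchings[bi][0] <= ev.time:
            _, node = branchings[bi]
            truth[node] = alleles[node]
            for ch in tree.children[node]:
                alleles[ch] = alleles[node].copy()
                orders[ch] = list(orders[node])
            bi += 1
        if ev.kind == "mutation":
            cur = alleles[ev.branch][ev.locus_start]
            alleles[ev.branch][ev.locus_start] = (cur + 1 + rng.integers(3)) % 4
        elif ev.kind == "hre":
            src, dst = ev.source_branch, ev.branch
            if ev.locus_start < 0:
                runs = _collinear_intervals(orders[src], orders[dst])
                weights = np.array([r * (r + 1) / 2 for _, r in runs], dtype=float)
                ri = int(rng.choice(len(runs), p=weights / weights.sum()))
                r_start, r_len = runs[ri]
                off, length = _sample_segment(config, r_len, rng)
                loci = [orders[src][r_start + off + k].locus for k in range(length)]
            else:
                loci = list(range(ev.locus_start, ev.locus_end + 1))
            loci_arr = np.array(loci)
            ev.donor_mismatches = int(
                (alleles[src][loci_arr] != alleles[dst][loci_arr]).sum()
            )
            alleles[dst][loci_arr] = alleles[src][loci_arr]
            if ev.locus_start < 0:
                ev.locus_start, ev.locus_end = min(loci), max(loci)
        elif ev.kind == "inversion":
            orders[ev.branch] = apply_inversion(
                orders[ev.branch], ev.locus_start, ev.locus_end
            )
    while bi < len(branchings):
        _, node = branchings[bi]
        truth[node] = alleles[node]
        for ch in tree.children[node]:
            alleles[ch] = alleles[node].copy()
            orders[ch] = list(orders[node])
        bi += 1

    for leaf in tree.leaf_ids:
        truth[leaf] = alleles[leaf]

    leaf_matrix = np.full((tree.n_leaves, n), MISSING, dtype=np.int64)
    stop = depths.max()
    for leaf in tree.leaf_ids:
        row = truth[leaf].copy()
        flips = rng.uniform(size=n) < config.error_rate
        for locus in np.flatnonzero(flips):
            row[locus] = (row[locus] + 1 + rng.integers(3)) % 4
            events.append(TrueEvent("error", stop, leaf, int(locus), int(locus)))
        masked = rng.uniform(size=n) < config.missing_rate
        for locus in np.flatnonzero(masked):
            events.append(TrueEvent("missing", stop, leaf, int(locus), int(locus)))
        row[masked] = MISSING
        leaf_matrix[leaf] = row

    leaf_orders = [orders.get(leaf, list(base_order)) for leaf in range(tree.n_leaves)]

    events.sort(key=lambda e: e.time)
    flag_nullified(events)
    return SimResult(config, tree, events, truth, leaf_matrix, leaf_orders)


def flag_nullified(events: list[TrueEvent]) -> list[TrueEvent]:
    """Mark events that leave no detectable same-branch evidence.

    A mutation is nullified by a later mutation at the same locus or a
    later recombination covering it on the same branch; a recombination
    is nullified when donor and recipient differed at <=1 SNP at event
    time, or when a later recombination on the same branch overwrites
    its whole range.  Cross-branch nullification is deliberately not
    flagged.
    """
    per_branch: dict[int, list[TrueEvent]] = {}
    for ev in events:
        if ev.kind in ("mutation", "hre"):
            per_branch.setdefault(ev.branch, []).append(ev)
    for evs in per_branch.values():
        evs.sort(key=lambda e: e.time)
        for i, ev in enumerate(evs):
            later = evs[i + 1:]
            if ev.kind == "mutation":
                ev.nullified = any(
                    (l.kind == "mutation" and l.locus_start == ev.locus_start)
                    or (l.kind == "hre" and l.locus_start <= ev.locus_start <= l.locus_end)
                    for l in later
                )
            else:
                overwritten = any(
                    l.kind == "hre"
                    and l.locus_start <= ev.locus_start
                    and l.locus_end >= ev.locus_end
                    for l in later
                )
                ev.nullified = overwritten or (0 <= ev.donor_mismatches <= 1)
    return events


def simulate(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Full generator: tree, events, realisation, noise, nullified flags."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    events = simulate_events(tree, config, rng)
    return realize_alleles(tree, events, config, rng)


# ---------------------------------------------------------------------------
# truth output
# ---------------------------------------------------------------------------


def write_truth_tsv(events: list[TrueEvent], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "branch", "source_branch", "time",
                    "locus_start", "locus_end", "nullified"])
        for ev in events:
            w.writerow([
                ev.kind, ev.branch,
                "" if ev.source_branch is None else ev.source_branch,
                f"{ev.time:.6f}", ev.locus_start, ev.locus_end,
                int(ev.nullified),
            ])
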