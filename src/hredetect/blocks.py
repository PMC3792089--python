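"""Partitioning genomes into locally collinear blocks.

A block is a string of signed SNPs.  A genome *agrees* with a block when
its SNP layout shows no evidence of a rearrangement inside the block:
the block string, after deleting loci absent from the genome, must occur
in the genome up to (a) insertions of the genome's duplicated loci,
(b) reading a region in reverse complement, and (c) continuing the match
across a contig end at any compatible end of another contig (the
jump-over-contig step, enumerated over all alternatives).

Blocks are grown greedily from a seed SNP, adding the SNP adjacent to a
block end in some genome whenever every genome still agrees; a block is
emitted when no adjacent candidate extends it in either direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import MISSING, GenomeLayout, Occurrence, SignedSNP, complement

log = logging.getLogger(__name__)

DEFAULT_JUMP_CAP = 64


@dataclass
class Block:
    """An ordered string of signed SNPs with no internal rearrangement."""

    block_id: int
    snps: list[SignedSNP]

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def loci(self) -> frozenset[int]:
        return frozenset(s.locus for s in self.snps)

    def reverse_complement(self) -> "Block":
        return Block(self.block_id, [s.reverse() for s in reversed(self.snps)])

    def canonical(self) -> "Block":
        """Lexicographically smaller of the string and its reverse complement."""
        rc = self.reverse_complement()
        key = [(s.locus, s.orient) for s in self.snps]
        rkey = [(s.locus, s.orient) for s in rc.snps]
        return self if key <= rkey else rc


@dataclass
class BlockSet:
    blocks: list[Block]
    covered: dict[int, list[int]] = field(default_factory=dict)

    @property
    def increased_snp_count(self) -> int:
        """Sum of block lengths; exceeds the locus count when blocks overlap."""
        return sum(len(b) for b in self.blocks)

    @property
    def overlapping_loci(self) -> dict[int, list[int]]:
        return {l: ids for l, ids in self.covered.items() if len(ids) > 1}


class _Matcher:
    """Depth-first matcher for one (genome, block-string) agreement test."""

    def __init__(self, layout: GenomeLayout, jump_cap: int):
        self.layout = layout
        self.dups = layout.duplicated_loci
        self.jump_cap = jump_cap
        self.jumps_used = 0
        self.capped = False

    def match(self, seq: list[tuple[int, SignedSNP]]) -> Optional[dict[int, Occurrence]]:
        """Try to place ``seq`` (pairs of block index, signed SNP, already
        restricted to loci present in the genome); returns a witness map
        block-index -> occurrence on success."""
        if not seq:
            return {}
        first = seq[0][1]
        for occ in self.layout.occurrences(first.locus):
            for direction in (1, -1):
                if self._symbol(occ.contig, occ.index, direction) == first:
                    witness: dict[int, Occurrence] = {}
                    if self._walk(occ.contig, occ.index, direction, seq, 0,
                                  frozenset([occ.contig]), witness):
                        return witness
        return None

    def _symbol(self, contig: int, idx: int, direction: int) -> SignedSNP:
        snp = self.layout.contigs[contig][idx]
        return snp if direction > 0 else snp.reverse()

    def _occurrence(self, contig: int, idx: int) -> Occurrence:
        snp = self.layout.contigs[contig][idx]
        return Occurrence(snp, contig, idx, self.layout.positions[contig][idx])

    def _walk(self, contig, idx, direction, seq, s_idx, used, witness) -> bool:
        contig_len = len(self.layout.contigs[contig])
        while True:
            if s_idx == len(seq):
                return True
            if idx < 0 or idx >= contig_len:
                return self._jump(seq, s_idx, used, witness)
            sym = self._symbol(contig, idx, direction)
            want_bidx, want = seq[s_idx]
            if sym == want:
                if want.locus in self.dups:
                    # duplicated locus: branch between matching and skipping
                    witness[want_bidx] = self._occurrence(contig, idx)
                    if self._walk(contig, idx + direction, direction, seq,
                                  s_idx + 1, used, witness):
                        return True
                    del witness[want_bidx]
                    idx += direction  # skip branch
                    continue
                witness[want_bidx] = self._occurrence(contig, idx)
                idx += direction
                s_idx += 1
                continue
            if sym.locus in self.dups:
                idx += direction  # an inserted duplicated SNP is skippable
                continue
            return False  # rearrangement evidence before the contig end

    def _jump(self, seq, s_idx, used, witness) -> bool:
        """Resume the match at any free contig end (enumerating alternatives)."""
        for contig in range(len(self.layout.contigs)):
            if contig in used:
                continue
            n = len(self.layout.contigs[contig])
            if n == 0:
                continue
            for idx, direction in ((0, 1), (n - 1, -1)):
                self.jumps_used += 1
                if self.jumps_used > self.jump_cap:
                    if not self.capped:
                        self.capped = True
                        log.warning(
                            "jump-over-contig enumeration cap (%d) hit for "
                            "genome %s; agreement test truncated",
                            self.jump_cap, self.layout.genome_id,
                        )
                    return False
                saved = dict(witness)
                if self._walk(contig, idx, direction, seq, s_idx,
                              used | {contig}, witness):
                    return True
                witness.clear()
                witness.update(saved)
        return False


def _restrict(block: Block, layout: GenomeLayout) -> list[tuple[int, SignedSNP]]:
    present = layout.present_loci
    return [(i, s) for i, s in enumerate(block.snps) if s.locus in present]


def agrees_witness(
    layout: GenomeLayout, block: Block, jump_cap: int = DEFAULT_JUMP_CAP
) -> tuple[bool, Optional[dict[int, Occurrence]]]:
    """Agreement test returning the match witness (block index -> occurrence).

    Loci absent from the genome never cause disagreement; an empty
    restriction agrees trivially.  Reverse-complement matches are covered
    by walking contigs in both directions, so agreement with a block and
    with its reverse complement coincide.
    """
    if not block.snps:
        raise ValueError("agreement test against an empty block")
    seq = _restrict(block, layout)
    witness = _Matcher(layout, jump_cap).match(seq)
    return (witness is not None), witness


def agrees(layout: GenomeLayout, block: Block, jump_cap: int = DEFAULT_JUMP_CAP) -> bool:
    return agrees_witness(layout, block, jump_cap)[0]


# ---------------------------------------------------------------------------
# greedy extension
# ---------------------------------------------------------------------------


def _adjacent_candidates(layout: GenomeLayout, end: SignedSNP) -> list[SignedSNP]:
    """SNPs immediately following ``end`` (in the block's reading direction)
    at any occurrence of ``end`` in the genome."""
    out: list[SignedSNP] = []
    for occ in layout.occurrences(end.locus):
        contig = layout.contigs[occ.contig]
        if occ.snp == end and occ.index + 1 < len(contig):
            out.append(contig[occ.index + 1])
        elif occ.snp == end.reverse() and occ.index - 1 >= 0:
            out.append(contig[occ.index - 1].reverse())
    return out


def extend_block(
    seed: SignedSNP,
    layouts: list[GenomeLayout],
    block_id: int = 0,
    jump_cap: int = DEFAULT_JUMP_CAP,
) -> Block:
    """Grow a maximal block from a seed SNP.

    Candidates come from genomes in input order, forward direction before
    reverse; each candidate is tested at most once per block end, and is
    accepted only when every genome agrees with the extended string.
    """
    snps = [seed]

    def try_extend_right() -> bool:
        loci = {s.locus for s in snps}
        tested: set[SignedSNP] = set()
        for layout in layouts:
            for cand in _adjacent_candidates(layout, snps[-1]):
                if cand.locus in loci or cand in tested:
                    continue
                tested.add(cand)
                candidate = Block(block_id, snps + [cand])
                if all(agrees(g, candidate, jump_cap) for g in layouts):
                    snps.append(cand)
                    return True
        return False

    changed = True
    while changed:
        changed = False
        # forward direction: extend the right end
        while try_extend_right():
            changed = True
        # reverse direction: flip the block and extend the (old left) end
        snps.reverse()
        for i, s in enumerate(snps):
            snps[i] = s.reverse()
        while try_extend_right():
            changed = True
        snps.reverse()
        for i, s in enumerate(snps):
            snps[i] = s.reverse()
    return Block(block_id, snps).canonical()


def get_blocks(
    layouts: list[GenomeLayout], jump_cap: int = DEFAULT_JUMP_CAP
) -> BlockSet:
    """Partition all loci into maximal blocks (greedy, order-deterministic).

    Seeds are taken genome by genome in input order, occurrence by
    occurrence in layout order; a locus already included in a block is
    never used as a seed, but extension may re-include covered loci,
    which is how overlapping blocks arise.
    """
    if len(layouts) < 2:
        raise ValueError("block partitioning needs at least 2 genomes")
    blocks: list[Block] = []
    covered: dict[int, list[int]] = {}
    for layout in layouts:
        for contig in layout.contigs:
            for snp in contig:
                if snp.locus in covered:
                    continue
                block = extend_block(snp, layouts, block_id=len(blocks), jump_cap=jump_cap)
                blocks.append(block)
                for s in block.snps:
                    covered.setdefault(s.locus, []).append(block.block_id)
    return BlockSet(blocks, covered)


# ---------------------------------------------------------------------------
# allele projection
# ---------------------------------------------------------------------------


def project_alleles(block: Block, data) -> dict[str, np.ndarray]:
    """Per-genome allele rows of a block, in block SNP order.

    Alleles of occurrences recorded on the opposite strand of the block's
    reference orientation are complemented; absent loci give MISSING; for
    duplicated loci the occurrence chosen by the agreement witness is used.
    """
    known = set(data.loci)
    for s in block.snps:
        if s.locus not in known:
            raise ValueError(f"block references unknown locus {s.locus}")
    rows: dict[str, np.ndarray] = {}
    m = len(block.snps)
    for layout in data.layouts:
        ok, witness = agrees_witness(layout, block)
        row = np.full(m, MISSING, dtype=np.int64)
        if ok and witness is not None:
            for b_idx, occ in witness.items():
                code = data.alleles[layout.genome_id][(occ.contig, occ.index)]
                if occ.snp.orient != block.snps[b_idx].orient:
                    code = complement(code)
                row[b_idx] = code
        else:  # genome disagrees (possible only for externally supplied blocks)
            for b_idx, s in enumerate(block.snps):
                occs = layout.occurrences(s.locus)
                if occs:
                    code = data.alleles[layout.genome_id][(occs[0].contig, occs[0].index)]
                    if occs[0].snp.orient != s.orient:
                        code = complement(code)
                    row[b_idx] = code
        rows[layout.genome_id] = row
    return rows
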