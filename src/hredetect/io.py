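"""File formats: SNP matrix TSV, Newick trees, event tables and summaries.

The SNP matrix is a plain TSV with columns
``locus_id  genome_id  contig_id  position  strand  allele``:
one row per SNP occurrence, 1-based positions within a contig, strand
``+``/``-``, allele as read on the recorded strand.  Missing (genome,
locus) pairs simply have no row.  Trees are rooted Newick; parsing goes
through dendropy.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .core import (
    MISSING,
    EventCall,
    GenomeLayout,
    SignedSNP,
    complement,
    decode_allele,
    encode_allele,
)
from .tree import PhyloTree, _TmpNode

COLUMNS = ["locus_id", "genome_id", "contig_id", "position", "strand", "allele"]


@dataclass
class SnpData:
    """Parsed SNP matrix: layouts plus per-occurrence allele codes."""

    loci: list[int]
    layouts: list[GenomeLayout]
    #: alleles[genome_id][(contig_index, occurrence_index)] -> code as read
    #: on the occurrence's recorded strand
    alleles: dict[str, dict[tuple[int, int], int]]

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.layouts]

    def layout_of(self, genome_id: str) -> GenomeLayout:
        for g in self.layouts:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def forward_allele(self, genome_id: str, locus: int) -> int:
        """Allele of ``locus`` in ``genome_id`` on the + strand (first
        occurrence for duplicated loci); MISSING if absent."""
        layout = self.layout_of(genome_id)
        occs = layout.occurrences(locus)
        if not occs:
            return MISSING
        occ = occs[0]
        code = self.alleles[genome_id][(occ.contig, occ.index)]
        return code if occ.snp.orient > 0 else complement(code)


def read_snp_matrix(path) -> SnpData:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = [c for c in COLUMNS if c not in (reader.fieldnames or [])]
        if missing_cols:
            raise ValueError(f"SNP matrix is missing columns: {missing_cols}")
        for rec in reader:
            rows.append(rec)

    # group by genome (file order), then contig (first appearance), sort by position
    genomes: dict[str, dict[str, list[tuple[int, int, int, int]]]] = {}
    seen_pos = set()
    for rec in rows:
        locus = int(rec["locus_id"])
        genome = rec["genome_id"]
        contig = rec["contig_id"]
        pos = int(rec["position"])
        strand = rec["strand"]
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {strand!r} (use '+' or '-')")
        code = encode_allele(rec["allele"])
        if code == MISSING:
            raise ValueError(f"allele {rec['allele']!r} outside A/C/G/T")
        key = (genome, contig, pos)
        if key in seen_pos:
            raise ValueError(f"duplicate (genome, contig, position) row: {key}")
        seen_pos.add(key)
        genomes.setdefault(genome, {}).setdefault(contig, []).append(
            (pos, locus, 1 if strand == "+" else -1, code)
        )

    loci = sorted({int(r["locus_id"]) for r in rows})
    layouts: list[GenomeLayout] = []
    alleles: dict[str, dict[tuple[int, int], int]] = {}
    for genome, contigs in genomes.items():
        contig_lists: list[list[SignedSNP]] = []
        pos_lists: list[list[int]] = []
        allele_map: dict[tuple[int, int], int] = {}
        for ci, (contig_id, occ) in enumerate(contigs.items()):
            occ.sort(key=lambda t: t[0])
            contig_lists.append([SignedSNP(locus, orient) for _, locus, orient, _ in occ])
            pos_lists.append([pos for pos, *_ in occ])
            for idx, (_, _, _, code) in enumerate(occ):
                allele_map[(ci, idx)] = code
        layouts.append(GenomeLayout(genome, contig_lists, pos_lists))
        alleles[genome] = allele_map
    return SnpData(loci, layouts, alleles)


def write_snp_matrix(data: SnpData, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for layout in data.layouts:
            for ci, contig in enumerate(layout.contigs):
                for idx, snp in enumerate(contig):
                    code = data.alleles[layout.genome_id][(ci, idx)]
                    writer.writerow(
                        [
                            snp.locus,
                            layout.genome_id,
                            f"c{ci}",
                            layout.positions[ci][idx],
                            "+" if snp.orient > 0 else "-",
                            decode_allele(code),
                        ]
                    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_tree(path, genome_ids: Optional[list[str]] = None, allow_unrooted: bool = False) -> PhyloTree:
    """Read a rooted Newick tree; leaf labels must match the SNP genomes.

    A trifurcating (unrooted-style) root is rejected unless
    ``allow_unrooted`` is set, in which case the tree is returned as-is so
    the caller can re-root it (e.g. with
    :func:`hredetect.tree.root_by_homoplasy`).
    """
    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    return _convert_dendropy(dtree, genome_ids, allow_unrooted)


def read_tree_string(newick: str, genome_ids: Optional[list[str]] = None, allow_unrooted: bool = False) -> PhyloTree:
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    return _convert_dendropy(dtree, genome_ids, allow_unrooted)


def _convert_dendropy(dtree: "dendropy.Tree", genome_ids, allow_unrooted) -> PhyloTree:
    seed = dtree.seed_node
    n_root_children = len(seed.child_nodes())
    if n_root_children > 2 and not allow_unrooted:
        raise ValueError(
            "tree root is multifurcating (unrooted-style Newick); pass "
            "allow_unrooted=True and re-root, e.g. by homoplasy count"
        )

    def conv(dnode) -> _TmpNode:
        length = dnode.edge.length if dnode.edge.length is not None else 1.0
        name = dnode.taxon.label if dnode.taxon is not None else None
        tmp = _TmpNode(length=float(length), name=name)
        for ch in dnode.child_nodes():
            tmp.children.append(conv(ch))
        return tmp

    root = conv(seed)
    root.length = 0.0
    tree = PhyloTree.from_tmp(root)
    labels = [tree.genome_ids[i] for i in tree.leaf_ids]
    if any(l is None for l in labels):
        raise ValueError("tree contains unlabeled leaves")
    if genome_ids is not None:
        extra = sorted(set(labels) - set(genome_ids))
        absent = sorted(set(genome_ids) - set(labels))
        if extra or absent:
            raise ValueError(
                f"tree/SNP matrix genome mismatch: labels only in tree {extra}, "
                f"only in SNP matrix {absent}"
            )
    return tree


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# event output
# ---------------------------------------------------------------------------


def events_to_rows(
    events: list[EventCall],
    blocks=None,
    data: Optional[SnpData] = None,
) -> list[dict]:
    """Flatten event calls for tabular output.

    When ``blocks``/``data`` are given, block-local SNP indices are
    augmented with locus ids and, per leaf genome carrying both flanking
    loci, the genomic positions of the event's flanking SNPs (compact
    ``genome:contig:start-end`` list).
    """
    rows = []
    for ev in events:
        row = {
            "kind": ev.kind,
            "block_id": ev.block_id,
            "dest_node": ev.dest_node,
            "source": "" if ev.source is None else str(ev.source),
            "j_start": ev.j_start,
            "j_end": ev.j_end,
            "allele_from": decode_allele(ev.allele_from),
            "allele_to": decode_allele(ev.allele_to),
            "cycle_nodes": (
                ",".join(map(str, ev.cycle_nodes)) if ev.cycle_nodes else ""
            ),
            "locus_start": "",
            "locus_end": "",
            "flank_positions": "",
        }
        if blocks is not None:
            snps = blocks.blocks[ev.block_id].snps
            lo, hi = snps[ev.j_start].locus, snps[ev.j_end].locus
            row["locus_start"], row["locus_end"] = lo, hi
            if data is not None:
                flanks = []
                for layout in data.layouts:
                    o1, o2 = layout.occurrences(lo), layout.occurrences(hi)
                    if o1 and o2:
                        flanks.append(
                            f"{layout.genome_id}:c{o1[0].contig}:"
                            f"{o1[0].position}-{o2[0].position}"
                        )
                row["flank_positions"] = ";".join(flanks)
        rows.append(row)
    return rows


def write_events_tsv(events, path, blocks=None, data=None) -> None:
    rows = events_to_rows(events, blocks, data)
    fieldnames = [
        "kind", "block_id", "dest_node", "source", "j_start", "j_end",
        "locus_start", "locus_end", "allele_from", "allele_to",
        "cycle_nodes", "flank_positions",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def summary_dict(events: list[EventCall], tree: PhyloTree) -> dict:
    per_kind: dict[str, int] = {}
    per_node: dict[str, dict[str, int]] = {}
    for ev in events:
        per_kind[ev.kind] = per_kind.get(ev.kind, 0) + 1
        node = per_node.setdefault(str(ev.dest_node), {})
        node[ev.kind] = node.get(ev.kind, 0) + 1
    return {
        "n_events": len(events),
        "per_kind": per_kind,
        "per_node": per_node,
        "n_nodes": tree.n_nodes,
        "n_leaves": tree.n_leaves,
    }


def write_summary_json(events, tree, path, extra: Optional[dict] = None) -> None:
    payload = summary_dict(events, tree)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
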