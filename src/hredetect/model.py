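"""Model/Results interface tying the detection pipeline together.

:class:`HreModel` holds the data (SNP matrix + rooted species tree) and
the event weights; :meth:`HreModel.fit` partitions the genomes into
locally collinear blocks, reconstructs ancestral alleles by weighted
small parsimony, runs the per-node source dynamic program, traces
allele origins for inheritance cycles, and returns an
:class:`HreResults` carrying the event calls, per-block weights and
summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import io as hio
from .blocks import BlockSet, get_blocks, project_alleles, DEFAULT_JUMP_CAP
from .core import MISSING, EventCall, Weights
from .engine import assign_events, total_event_weight, trace_origins
from .parsimony import ancestral_states
from .tree import PhyloTree


class HreModel:
    """Minimum-weight mutation/error/recombination reconstruction.

    Parameters
    ----------
    data : SnpData
        Parsed SNP matrix (loci, genome layouts, per-occurrence alleles).
    tree : PhyloTree
        Rooted species tree whose leaves are the genomes in ``data``.
    weights : Weights, optional
        Event costs; validated on construction.
    outgroup : bool
        Enable the out-group donor state (affine opening/extension cost).
    jump_cap : int
        Enumeration cap for jump-over-contig alternatives per agreement
        test in the block builder.
    """

    def __init__(
        self,
        data: hio.SnpData,
        tree: PhyloTree,
        weights: Optional[Weights] = None,
        outgroup: bool = True,
        jump_cap: int = DEFAULT_JUMP_CAP,
    ):
        self.data = data
        self.tree = tree
        self.weights = weights or Weights()
        self.weights.validate()
        self.outgroup = outgroup
        self.jump_cap = jump_cap
        missing = set(data.genome_ids) - set(tree.leaf_of_genome)
        extra = set(tree.leaf_of_genome) - set(data.genome_ids)
        if missing or extra:
            raise ValueError(
                f"genome/leaf mismatch: not in tree {sorted(missing)}, "
                f"not in SNP matrix {sorted(extra)}"
            )

    @classmethod
    def from_files(
        cls, snp_path, tree_path, weights: Optional[Weights] = None, **kw
    ) -> "HreModel":
        data = hio.read_snp_matrix(snp_path)
        tree = hio.read_tree(tree_path, genome_ids=data.genome_ids)
        return cls(data, tree, weights=weights, **kw)

    def fit(self) -> "HreResults":
        blocks = get_blocks(self.data.layouts, jump_cap=self.jump_cap)
        events: list[EventCall] = []
        block_weights: list[float] = []
        parsimony_weights: list[float] = []
        matrices: list[np.ndarray] = []
        for block in blocks.blocks:
            rows = project_alleles(block, self.data)
            leaf_matrix = np.stack(
                [rows[self.tree.genome_ids[i]] for i in self.tree.leaf_ids]
            )
            states, col_w = ancestral_states(self.tree, leaf_matrix, self.weights)
            calls, weight = assign_events(
                states, self.tree, self.weights,
                block_id=block.block_id, outgroup=self.outgroup,
            )
            calls.extend(
                trace_origins(calls, self.tree, len(block), block_id=block.block_id)
            )
            events.extend(calls)
            block_weights.append(weight)
            parsimony_weights.append(float(col_w.sum()))
            matrices.append(states)
        return HreResults(
            self, blocks, events, block_weights, parsimony_weights, matrices
        )


@dataclass
class HreResults:
    """Fitted event assignment with diagnostics."""

    model: HreModel
    blocks: BlockSet
    events: list[EventCall]
    block_weights: list[float]
    parsimony_weights: list[float]
    block_states: list[np.ndarray]

    @property
    def total_weight(self) -> float:
        return float(sum(self.block_weights))

    @property
    def parsimony_weight(self) -> float:
        """Total weight if only mutations and errors were allowed."""
        return float(sum(self.parsimony_weights))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.kind] = out.get(ev.kind, 0) + 1
        return out

    def hre_calls(self, include_outgroup: bool = False) -> list[EventCall]:
        kinds = {"hre", "outgroup_hre"} if include_outgroup else {"hre"}
        return [ev for ev in self.events if ev.kind in kinds]

    def events_frame(self) -> pd.DataFrame:
        rows = hio.events_to_rows(self.events, self.blocks, self.model.data)
        return pd.DataFrame(rows)

    def node_counts(self) -> pd.DataFrame:
        """Events per destination node: m (mutations), e (errors), x (HREs)."""
        idx = range(self.model.tree.n_nodes)
        table = pd.DataFrame(0, index=idx, columns=["m", "e", "x", "outgroup"])
        key = {"mutation": "m", "error": "e", "hre": "x", "outgroup_hre": "outgroup"}
        for ev in self.events:
            if ev.kind in key:
                table.loc[ev.dest_node, key[ev.kind]] += 1
        return table

    def summary(self) -> str:
        tree = self.model.tree
        counts = self.counts()
        w = self.model.weights
        lines = [
            "Recombination event detection summary",
            "=====================================",
            f"genomes: {len(self.model.data.layouts)}    loci: {len(self.model.data.loci)}"
            f"    tree nodes: {tree.n_nodes}",
            f"blocks: {len(self.blocks.blocks)}    increased SNPs: "
            f"{self.blocks.increased_snp_count}    overlapping loci: "
            f"{len(self.blocks.overlapping_loci)}",
            f"weights: w_m={w.w_m} w_x={w.w_x} w_e={w.w_e} w_o={w.w_o} w_t={w.w_t}",
            f"total weight: {self.total_weight:.2f}    "
            f"(mutations/errors only: {self.parsimony_weight:.2f})",
            "",
            "event counts:",
        ]
        for kind in ("mutation", "error", "hre", "outgroup_hre", "outgroup_evidence"):
            lines.append(f"  {kind:<18} {counts.get(kind, 0)}")
        busiest = self.node_counts().sum(axis=1).sort_values(ascending=False).head(5)
        lines.append("")
        lines.append("busiest destination nodes (m+e+x):")
        for node, cnt in busiest.items():
            if cnt > 0:
                lines.append(f"  node {node:<4} {int(cnt)}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write blocks.tsv, events.tsv and summary.json under ``outdir``."""
        import csv
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "blocks.tsv", "w", newline="") as fh:
            wtr = csv.writer(fh, delimiter="\t", lineterminator="\n")
            wtr.writerow(["block_id", "length", "snps", "overlaps"])
            for b in self.blocks.blocks:
                overl = any(
                    len(self.blocks.covered[s.locus]) > 1 for s in b.snps
                )
                wtr.writerow([
                    b.block_id, len(b),
                    ",".join(str(s) for s in b.snps), int(overl),
                ])
        hio.write_events_tsv(
            self.events, outdir / "events.tsv", self.blocks, self.model.data
        )
        hio.write_summary_json(
            self.events, self.model.tree, outdir / "summary.json",
            extra={
                "total_weight": self.total_weight,
                "parsimony_weight": self.parsimony_weight,
                "n_blocks": len(self.blocks.blocks),
                "increased_snp_count": self.blocks.increased_snp_count,
            },
        )
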