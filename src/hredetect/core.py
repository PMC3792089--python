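"""Core domain types shared across the package.

Alleles are stored as small integer codes (``A C G T`` -> ``0 1 2 3``) with
``MISSING = -1``; complementation is ``3 - code``.  A *signed SNP* is a SNP
locus together with a reading orientation, the alphabet over which locally
collinear blocks are written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

MISSING = -1
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

FORWARD = 1
REVERSE = -1

#: Sentinel used as an event source when the donor lies outside the tree.
OUTGROUP = "OUTGROUP"


def encode_allele(base: str) -> int:
    """Map a base letter to its integer code; '.'/'N'/'-' mean missing."""
    if base in _CODE:
        return _CODE[base]
    if base in (".", "N", "-", ""):
        return MISSING
    raise ValueError(f"allele {base!r} is not one of A, C, G, T or missing")


def decode_allele(code: int) -> str:
    return "." if code == MISSING else _BASES[code]


def complement(code: int) -> int:
    """Watson-Crick complement of an allele code (missing stays missing)."""
    return MISSING if code == MISSING else 3 - code


class SignedSNP(NamedTuple):
    """A SNP locus read in a given orientation (+1 forward, -1 reverse)."""

    locus: int
    orient: int

    def reverse(self) -> "SignedSNP":
        return SignedSNP(self.locus, -self.orient)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{'-' if self.orient < 0 else ''}{self.locus}"


class Occurrence(NamedTuple):
    """One placement of a signed SNP on a contig of a genome."""

    snp: SignedSNP
    contig: int
    index: int          # 0-based index along the contig's occurrence list
    position: int       # 1-based genomic coordinate within the contig


@dataclass
class GenomeLayout:
    """A genome as an ordered list of contigs of signed SNP occurrences.

    Adjacency is meaningful only within a contig; the order of the contigs
    themselves carries no information.  A locus may be absent (missing),
    occur once, or occur several times (a duplicated SNP).
    """

    genome_id: str
    contigs: list[list[SignedSNP]]
    positions: Optional[list[list[int]]] = None

    def __post_init__(self) -> None:
        if self.positions is None:
            self.positions = [list(range(1, len(c) + 1)) for c in self.contigs]
        self._index: dict[int, list[Occurrence]] = {}
        for ci, contig in enumerate(self.contigs):
            for i, snp in enumerate(contig):
                occ = Occurrence(snp, ci, i, self.positions[ci][i])
                self._index.setdefault(snp.locus, []).append(occ)

    @property
    def present_loci(self) -> frozenset[int]:
        return frozenset(self._index)

    @property
    def duplicated_loci(self) -> frozenset[int]:
        """Loci occurring more than once in this genome (the set D(G))."""
        return frozenset(l for l, occ in self._index.items() if len(occ) > 1)

    def occurrences(self, locus: int) -> list[Occurrence]:
        return self._index.get(locus, [])


@dataclass
class Weights:
    """Event costs for the minimum-weight reconstruction.

    w_m   cost of a mutation (SNP change on an edge into an internal node)
    w_x   cost of opening a recombination event with an in-tree donor
    w_e   cost of a sequencing error (SNP change on an edge into a leaf)
    w_o   opening cost of a recombination event from outside the tree
    w_t   per-SNP extension cost of an out-group event (affine, like a gap
          penalty: a run of L SNPs costs w_o + (L - 1) * w_t)

    The defaults (2, 3, 1, 3, 0.5) make one recombination event preferable
    to two mutations or three errors, but never to a single mutation or a
    pair of errors, and require a dense run of leaf mismatches before an
    out-group donor beats per-SNP error calls.
    """

    w_m: float = 2.0
    w_x: float = 3.0
    w_e: float = 1.0
    w_o: float = 3.0
    w_t: float = 0.5

    def validate(self) -> None:
        """Check the weight inequalities.

        ``w_e < w_m`` (errors are always cheaper than mutations) and
        positivity are hard requirements.  The calibration inequalities
        tying w_x to w_m and w_e only warn: infinite w_x/w_o deliberately
        disable recombination states, and alternative weight sets trade
        recall against precision.
        """
        for name in ("w_m", "w_x", "w_e", "w_o", "w_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"weight {name} must be positive")
        if not self.w_e < self.w_m:
            raise ValueError(
                "invalid weights: error weight < mutation weight is required "
                f"(got w_e={self.w_e}, w_m={self.w_m})"
            )
        if np.isfinite(self.w_x):
            problems = []
            if not self.w_x > self.w_m:
                problems.append("w_x > w_m")
            if not self.w_x < 2 * self.w_m:
                problems.append("w_x < 2*w_m")
            if not self.w_x > 2 * self.w_e:
                problems.append("w_x > 2*w_e")
            if not self.w_x <= 3 * self.w_e:
                problems.append("w_x <= 3*w_e")
            if problems:
                warnings.warn(
                    "weights outside the calibrated region (violated: "
                    + ", ".join(problems)
                    + "); recombination/mutation trade-offs will differ "
                    "from the default behaviour",
                    stacklevel=2,
                )


@dataclass
class EventCall:
    """A predicted event: mutation, error, recombination, or out-group call.

    ``j_start``/``j_end`` are inclusive block-local SNP indices (0-based);
    for point events they coincide.  ``source`` is a node id for in-tree
    recombination, :data:`OUTGROUP` for out-group calls, and ``None`` for
    mutations/errors charged against the parent edge.
    """

    kind: str                      # mutation | error | hre | outgroup_hre | outgroup_evidence
    block_id: int
    dest_node: int
    j_start: int
    j_end: int
    source: object = None
    allele_from: int = MISSING
    allele_to: int = MISSING
    cycle_nodes: Optional[tuple[int, ...]] = None

    @property
    def length(self) -> int:
        return self.j_end - self.j_start + 1

    def weight(self, weights: Weights) -> float:
        if self.kind == "mutation":
            return weights.w_m
        if self.kind == "error":
            return weights.w_e
        if self.kind == "hre":
            return weights.w_x
        if self.kind == "outgroup_hre":
            return weights.w_o + (self.length - 1) * weights.w_t
        return 0.0  # outgroup_evidence carries no weight of its own


def column_str(codes: Sequence[int]) -> str:
    """Render a vector of allele codes as a compact string (debugging)."""
    return "".join(decode_allele(c) for c in codes)
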