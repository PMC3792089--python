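import numpy as np
import pytest

from conftest import make_layout, snps
from oracles import oracle_agrees

from hredetect.blocks import Block, agrees, agrees_witness, extend_block, get_blocks, project_alleles
from hredetect.core import MISSING, GenomeLayout, SignedSNP
from hredetect.io import SnpData


def B(spec: str, block_id: int = 0) -> Block:
    return Block(block_id, snps(spec))


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def test_exact_substring_agrees():
    g = make_layout("G", "a b c")
    assert agrees(g, B("a b c"))


def test_missing_locus_never_breaks_agreement():
    g = make_layout("G", "a c")  # b absent
    assert agrees(g, B("a b c"))


def test_jump_over_contig():
    g = make_layout("G", "x a b", "c d y")
    assert agrees(g, B("a b c d"))


def test_internal_transposition_disagrees():
    g = make_layout("G", "a c b")
    assert not agrees(g, B("a b c"))
    assert not oracle_agrees(g, B("a b c"))


def test_duplicated_locus_skippable():
    # second occurrence of b is an insertion; the matcher may skip it
    g = make_layout("G", "a b b c")
    assert agrees(g, B("a b c"))
    # but a duplicate cannot rescue a genuine inversion of a non-dup locus
    g2 = make_layout("G2", "a b -c b c")
    assert agrees(g2, B("a b c")) == oracle_agrees(g2, B("a b c"))


def test_reverse_complement_symmetry():
    g = make_layout("G", "-c -b -a")
    blk = B("a b c")
    assert agrees(g, blk)
    assert agrees(g, blk.reverse_complement())


def _random_instance(rng):
    n_loci = int(rng.integers(2, 9))
    order = list(rng.permutation(n_loci))
    genomes = []
    for gi in range(int(rng.integers(1, 5))):
        seq = [SignedSNP(int(l), int(rng.choice([1, -1]))) if rng.uniform() < 0.2
               else SignedSNP(int(l), 1) for l in order]
        # random inversion of a window
        if rng.uniform() < 0.5 and n_loci >= 2:
            i = int(rng.integers(0, n_loci - 1))
            j = int(rng.integers(i + 1, n_loci + 1))
            seq[i:j] = [s.reverse() for s in reversed(seq[i:j])]
        # missing loci
        keep = [s for s in seq if rng.uniform() > 0.25]
        # at most one duplicated locus
        if keep and rng.uniform() < 0.4:
            dup = keep[int(rng.integers(len(keep)))]
            keep.insert(int(rng.integers(len(keep) + 1)), dup)
        # up to 2 contigs
        if len(keep) >= 2 and rng.uniform() < 0.5:
            cut = int(rng.integers(1, len(keep)))
            contigs = [keep[:cut], keep[cut:]]
        else:
            contigs = [keep]
        genomes.append(GenomeLayout(f"G{gi}", [c for c in contigs if c]))
    k = int(rng.integers(1, min(n_loci, 5) + 1))
    start = int(rng.integers(0, n_loci - k + 1))
    block_snps = [SignedSNP(int(l), 1) for l in order[start:start + k]]
    if rng.uniform() < 0.3:
        block_snps = [s.reverse() for s in reversed(block_snps)]
    return genomes, Block(0, block_snps)


def test_agreement_matches_exhaustive_matcher_on_random_instances():
    rng = np.random.default_rng(2024)
    checked = agreements = 0
    while checked < 300:
        genomes, block = _random_instance(rng)
        for g in genomes:
            got = agrees(g, block)
            want = oracle_agrees(g, block)
            assert got == want, (g.contigs, [str(s) for s in block.snps])
            checked += 1
            agreements += got
    assert 0 < agreements < checked  # both outcomes exercised


def test_agreement_is_monotone_under_sub_blocks():
    rng = np.random.default_rng(7)
    tried = 0
    while tried < 120:
        genomes, block = _random_instance(rng)
        if len(block) < 2:
            continue
        for g in genomes:
            if not agrees(g, block):
                continue
            for i in range(len(block)):
                for j in range(i, len(block)):
                    sub = Block(0, block.snps[i:j + 1])
                    assert agrees(g, sub)
            tried += 1


# ---------------------------------------------------------------------------
# extension and partitioning
# ---------------------------------------------------------------------------


def test_identical_genomes_one_block():
    gs = [make_layout(f"G{i}", "a b c d") for i in range(3)]
    blk = extend_block(SignedSNP(1, 1), gs)
    assert [s.locus for s in blk.snps] == [0, 1, 2, 3]
    bs = get_blocks(gs)
    assert len(bs.blocks) == 1
    assert bs.increased_snp_count == 4
    assert set(bs.covered) == {0, 1, 2, 3}


def test_inversion_splits_into_three_blocks():
    g1 = make_layout("G1", "a b c d")
    g2 = make_layout("G2", "a -c -b d")
    blk = extend_block(SignedSNP(1, 1), [g1, g2])
    assert sorted(s.locus for s in blk.snps) == [1, 2]
    bs = get_blocks([g1, g2])
    got = sorted(tuple(sorted(s.locus for s in b.snps)) for b in bs.blocks)
    assert got == [(0,), (1, 2), (3,)]
    assert not bs.overlapping_loci


def test_seed_present_in_single_genome_still_extends():
    # locus b only in G1; absence elsewhere never blocks extension
    g1 = make_layout("G1", "a b c")
    g2 = make_layout("G2", "a c")
    blk = extend_block(SignedSNP(1, 1), [g1, g2])
    assert sorted(s.locus for s in blk.snps) == [0, 1, 2]


def test_locus_next_to_inversion_endpoint_joins_two_blocks():
    # b is missing in G2, whose (c d) segment is inverted relative to G1:
    # b ends up in both the (a b) and the (b c d) block
    g1 = make_layout("G1", "a b c d")
    g2 = make_layout("G2", "a -d -c")
    bs = get_blocks([g1, g2])
    got = sorted(tuple(sorted(s.locus for s in b.snps)) for b in bs.blocks)
    assert got == [(0, 1), (1, 2, 3)]
    assert list(bs.overlapping_loci) == [1]
    assert bs.increased_snp_count == 5  # 4 loci + 1 overlap


def test_get_blocks_always_covers_every_locus():
    rng = np.random.default_rng(33)
    for _ in range(40):
        genomes, _ = _random_instance(rng)
        genomes = [g for g in genomes if g.present_loci]
        if len(genomes) < 2:
            continue
        bs = get_blocks(genomes)
        all_loci = set().union(*(g.present_loci for g in genomes))
        assert set(bs.covered) == all_loci
        assert bs.increased_snp_count >= len(all_loci)


def test_blocks_canonical_orientation_is_stable():
    gs = [make_layout(f"G{i}", "a b c") for i in range(2)]
    blk = extend_block(SignedSNP(2, 1), gs)
    assert blk.canonical().snps == blk.snps


# ---------------------------------------------------------------------------
# allele projection
# ---------------------------------------------------------------------------


def _data(layouts, allele_rows):
    """allele_rows: genome -> list of codes per occurrence, contig-major."""
    alleles = {}
    for layout in layouts:
        flat = iter(allele_rows[layout.genome_id])
        alleles[layout.genome_id] = {
            (ci, i): next(flat)
            for ci, contig in enumerate(layout.contigs)
            for i in range(len(contig))
        }
    return SnpData(sorted(set().union(*(g.present_loci for g in layouts))), layouts, alleles)


def test_projection_forward_block_is_identity():
    gs = [make_layout("G1", "a b c"), make_layout("G2", "a b c")]
    data = _data(gs, {"G1": [0, 1, 2], "G2": [3, 2, 1]})
    rows = project_alleles(B("a b c"), data)
    assert list(rows["G1"]) == [0, 1, 2]
    assert list(rows["G2"]) == [3, 2, 1]


def test_projection_complements_reverse_matches():
    # G2 carries the block in reverse complement: strand-relative alleles
    # must be complemented back to the block's reference orientation
    gs = [make_layout("G1", "a b c"), make_layout("G2", "-c -b -a")]
    data = _data(gs, {"G1": [0, 1, 2], "G2": [1, 2, 3]})
    rows = project_alleles(B("a b c"), data)
    assert list(rows["G1"]) == [0, 1, 2]
    assert list(rows["G2"]) == [0, 1, 2]  # 3-complements of reversed [1,2,3]


def test_projection_missing_stays_missing():
    gs = [make_layout("G1", "a b c"), make_layout("G2", "a c")]
    data = _data(gs, {"G1": [0, 1, 2], "G2": [0, 2]})
    rows = project_alleles(B("a b c"), data)
    assert rows["G2"][1] == MISSING


def test_projection_rejects_unknown_locus():
    gs = [make_layout("G1", "a b")]
    data = _data(gs, {"G1": [0, 1]})
    with pytest.raises(ValueError, match="unknown locus"):
        project_alleles(B("a b z"), data)
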