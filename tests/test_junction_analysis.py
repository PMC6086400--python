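"""Junction catalogs, gain/loss classification and cohort coverage tables."""

import numpy as np
import pytest

from persplice import (Genome, JunctionRecord, SequenceRecord, SnpHash,
                       SnpVariant)
from persplice.junction_analysis import (classify_polymorphic,
                                         coverage_change_table,
                                         extract_junctions, filter_by_support,
                                         support_grid)
from persplice.spliced_aligner import Block, SplicedAlignment

from conftest import random_seq


def _genome_with_motifs(donor="GT", acceptor="AG"):
    seq = list(random_seq(400, 77))
    seq[150], seq[151] = donor[0], donor[1]
    seq[228], seq[229] = acceptor[0], acceptor[1]
    return Genome([SequenceRecord("chr1", "".join(seq))])


def _spliced_aln(read_id, left_len=20, right_len=20):
    blocks = (Block(150 - left_len, left_len, 0), Block(230, right_len, left_len))
    j = JunctionRecord("chr1", 150, 229, "+", "GTAG", "GTAG", 0, "none")
    return SplicedAlignment(read_id, "chr1", "forward", blocks, (j,),
                            0, 0, 0, 0, 40)


class TestExtractJunctions:
    def test_support_counts_reads(self):
        genome = _genome_with_motifs()
        results = {f"r{i}": [_spliced_aln(f"r{i}")] for i in range(3)}
        catalog = extract_junctions(results, genome)
        (rec,) = catalog.values()
        assert rec.support == 3
        assert rec.ref_motif == "GTAG"

    def test_short_anchor_not_counted(self):
        genome = _genome_with_motifs()
        results = {"a": [_spliced_aln("a", left_len=7)],
                   "b": [_spliced_aln("b")]}
        catalog = extract_junctions(results, genome, min_anchor=8)
        (rec,) = catalog.values()
        assert rec.support == 1

    def test_strands_never_merge(self):
        genome = _genome_with_motifs()
        a = _spliced_aln("a")
        jm = JunctionRecord("chr1", 150, 229, "-", "CTAC", "CTAC", 0, "none")
        b = SplicedAlignment("b", "chr1", "forward", a.blocks, (jm,), 0, 0, 0, 0, 40)
        catalog = extract_junctions({"a": [a], "b": [b]}, genome)
        assert len(catalog) == 2


class TestClassify:
    def test_gain_gc_to_gt_donor(self):
        genome = _genome_with_motifs(donor="GC")
        snp = SnpVariant("chr1", 151, "C", "T", "hap1")
        catalog = extract_junctions({"r": [_spliced_aln("r")]}, genome, SnpHash([snp]))
        (rec,) = classify_polymorphic(catalog, genome, SnpHash([snp])).values()
        # GC-AG is itself canonical; build a truly noncanonical reference
        genome2 = _genome_with_motifs(donor="GG")
        snp2 = SnpVariant("chr1", 151, "G", "T", "hap1")
        catalog2 = extract_junctions({"r": [_spliced_aln("r")]}, genome2)
        (rec2,) = classify_polymorphic(catalog2, genome2, SnpHash([snp2])).values()
        assert rec2.polymorphic == "gain"
        assert rec2.ref_motif == "GGAG" and rec2.pers_motif == "GTAG"

    def test_loss_ag_to_ac_acceptor(self):
        genome = _genome_with_motifs()
        snp = SnpVariant("chr1", 229, "G", "C", "hap2")
        catalog = extract_junctions({"r": [_spliced_aln("r")]}, genome)
        (rec,) = classify_polymorphic(catalog, genome, SnpHash([snp])).values()
        assert rec.polymorphic == "loss"
        assert rec.pers_motif == "GTAC"

    def test_no_snp_is_none(self):
        genome = _genome_with_motifs()
        catalog = extract_junctions({"r": [_spliced_aln("r")]}, genome)
        (rec,) = classify_polymorphic(catalog, genome, SnpHash()).values()
        assert rec.polymorphic == "none"

    def test_never_both_gain_and_loss(self):
        from persplice.motifs import classify_motifs
        motifs = ["GTAG", "GGAG", "GTAC", "CTAC", "AAAA"]
        for ref in motifs:
            for pers in motifs:
                assert classify_motifs(ref, pers) in ("gain", "loss", "none")
                if classify_motifs(ref, pers) == "gain":
                    assert classify_motifs(pers, ref) == "loss"


def _cohort(genome, support_by_ind, snp, direction):
    """Catalogs with a single (possibly absent) junction per individual."""
    catalogs, genotypes = {}, {}
    key = ("chr1", 150, 229, "+")
    for ind, (support, carrier) in support_by_ind.items():
        cat = {}
        if support > 0:
            ref_motif = "GGAG" if direction == "gain" else "GTAG"
            cat[key] = JunctionRecord("chr1", 150, 229, "+", ref_motif,
                                      ref_motif, support, "none")
        catalogs[ind] = cat
        genotypes[ind] = SnpHash([snp]) if carrier else SnpHash()
    return catalogs, genotypes


class TestCoverageChange:
    def test_gain_matrix_hand_computed(self):
        genome = _genome_with_motifs(donor="GG")
        snp = SnpVariant("chr1", 151, "G", "T", "hap1")
        support = {"i1": (12, True), "i2": (13, True),
                   "i3": (0, False), "i4": (0, False)}
        catalogs, genotypes = _cohort(genome, support, snp, "gain")
        matrix, skipped = coverage_change_table(catalogs, genotypes, genome, "gain")
        # non-carrier avg 0 -> row 0; carrier avg 12.5 -> col (10,inf)
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 3] = 1
        assert np.array_equal(matrix, expected) and skipped == 0

    def test_loss_matrix_hand_computed(self):
        genome = _genome_with_motifs()
        snp = SnpVariant("chr1", 229, "G", "C", "hap1")
        support = {"i1": (0, True), "i2": (0, True),
                   "i3": (15, False), "i4": (15, False)}
        catalogs, genotypes = _cohort(genome, support, snp, "loss")
        matrix, skipped = coverage_change_table(catalogs, genotypes, genome, "loss")
        expected = np.zeros((4, 4), dtype=int)
        expected[3, 0] = 1
        assert np.array_equal(matrix, expected)

    def test_all_carriers_skipped(self):
        genome = _genome_with_motifs(donor="GG")
        snp = SnpVariant("chr1", 151, "G", "T", "hap1")
        support = {"i1": (5, True), "i2": (6, True)}
        catalogs, genotypes = _cohort(genome, support, snp, "gain")
        matrix, skipped = coverage_change_table(catalogs, genotypes, genome, "gain")
        assert matrix.sum() == 0 and skipped == 1

    def test_empty_cohort_raises(self):
        genome = _genome_with_motifs()
        with pytest.raises(ValueError, match="empty"):
            coverage_change_table({}, {}, genome, "gain")


class TestFilterBySupport:
    def make(self):
        genome = _genome_with_motifs(donor="GG")
        snp = SnpVariant("chr1", 151, "G", "T", "hap1")
        support = {"i1": (3, True), "i2": (7, True), "i3": (0, False)}
        return genome, *_cohort(genome, support, snp, "gain")

    def test_thresholds(self):
        genome, catalogs, genotypes = self.make()
        assert filter_by_support(catalogs, genome, genotypes, 2, 1) == 1
        assert filter_by_support(catalogs, genome, genotypes, 2, 2) == 1
        assert filter_by_support(catalogs, genome, genotypes, 5, 2) == 0
        assert filter_by_support(catalogs, genome, genotypes, 5, 1) == 1
        assert filter_by_support(catalogs, genome, genotypes, 10, 1) == 0

    def test_grid_monotone_in_both_thresholds(self):
        genome, catalogs, genotypes = self.make()
        grid = support_grid(catalogs, genome, genotypes).to_numpy()
        assert (np.diff(grid, axis=0) <= 0).all()  # more individuals required
        assert (np.diff(grid, axis=1) <= 0).all()  # more reads required
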