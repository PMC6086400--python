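"""Junction catalogs, splice-site-polymorphism classification, cohort tables.

A junction is *polymorphic-gain* when the reference donor/acceptor motif is
noncanonical but becomes canonical under an individual's alleles, and
*polymorphic-loss* for the reverse. Cohort analyses compare junction read
support between carriers and non-carriers of the splice-site allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import Genome
from .io_formats import JunctionRecord
from .motifs import classify_motifs, pair_strand
from .spliced_aligner import SnpHash

__all__ = [
    "extract_junctions",
    "extract_junctions_from_sam",
    "classify_polymorphic",
    "coverage_change_table",
    "filter_by_support",
    "support_grid",
    "COVERAGE_BINS",
]

# Average-coverage bins: 0, (0,2], (2,10], (10,+inf)
COVERAGE_BINS = ("0", "(0,2]", "(2,10]", "(10,+inf)")


def _coverage_bin(v: float) -> int:
    if v == 0:
        return 0
    if v <= 2:
        return 1
    if v <= 10:
        return 2
    return 3


def _motifs_for(genome: Genome, snp_hash: SnpHash, chrom: str,
                donor0: int, acceptor0: int) -> tuple[str, str]:
    refD, persD = snp_hash.personal_dinuc(genome, chrom, donor0)
    refA, persA = snp_hash.personal_dinuc(genome, chrom, acceptor0 - 1)
    return refD + refA, persD + persA


def extract_junctions(results, genome: Genome, snp_hash: SnpHash | None = None,
                      min_anchor: int = 8) -> dict:
    """Aggregate junctions from alignments into a catalog.

    results: {read id: [SplicedAlignment, ...]}. Support counts distinct
    uniquely mapped alignments containing the junction with at least
    min_anchor aligned bases on both sides. Motifs are (re)read from the
    genome and, for the personal motif, the SNP hash.
    """
    snp_hash = snp_hash if snp_hash is not None else SnpHash()
    catalog: dict[tuple, JunctionRecord] = {}
    for alns in results.values():
        if len(alns) != 1:
            continue
        aln = alns[0]
        for i, jrec in enumerate(aln.junctions):
            left, right = aln.blocks[i], aln.blocks[i + 1]
            if left.length < min_anchor or right.length < min_anchor:
                continue
            key = jrec.key()
            rec = catalog.get(key)
            if rec is None:
                ref_motif, pers_motif = _motifs_for(
                    genome, snp_hash, jrec.chrom, jrec.donor_pos0, jrec.acceptor_pos0)
                rec = JunctionRecord(jrec.chrom, jrec.donor_pos0, jrec.acceptor_pos0,
                                     jrec.strand, ref_motif, pers_motif, 0,
                                     classify_motifs(ref_motif, pers_motif))
                catalog[key] = rec
            rec.support += 1
    return dict(sorted(catalog.items()))


def extract_junctions_from_sam(sam_path, genome: Genome,
                               snp_hash: SnpHash | None = None,
                               min_anchor: int = 8) -> dict:
    """Junction catalog recovered from a SAM file (N CIGAR operations)."""
    import pysam

    snp_hash = snp_hash if snp_hash is not None else SnpHash()
    catalog: dict[tuple, JunctionRecord] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("NH") and rec.get_tag("NH") != 1:
                continue
            blocks = []  # (ref_start, length)
            pos = rec.reference_start
            introns = []
            for op, length in rec.cigartuples:
                if op == 0:  # M
                    if blocks and blocks[-1][0] + blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], blocks[-1][1] + length)
                    else:
                        blocks.append((pos, length))
                    pos += length
                elif op == 3:  # N
                    introns.append((pos, pos + length - 1, len(blocks) - 1))
                    pos += length
            for donor0, acceptor0, left_idx in introns:
                if blocks[left_idx][1] < min_anchor or blocks[left_idx + 1][1] < min_anchor:
                    continue
                chrom = rec.reference_name
                ref_motif, pers_motif = _motifs_for(genome, snp_hash, chrom,
                                                    donor0, acceptor0)
                strand = pair_strand(pers_motif[:2], pers_motif[2:])
                key = (chrom, donor0, acceptor0, strand)
                jrec = catalog.get(key)
                if jrec is None:
                    jrec = JunctionRecord(chrom, donor0, acceptor0, strand,
                                          ref_motif, pers_motif, 0,
                                          classify_motifs(ref_motif, pers_motif))
                    catalog[key] = jrec
                jrec.support += 1
    return dict(sorted(catalog.items()))


def classify_polymorphic(catalog: dict, genome: Genome, snp_hash: SnpHash) -> dict:
    """Annotate each junction as gain / loss / none under one individual's SNPs."""
    out = {}
    for key, rec in catalog.items():
        ref_motif, pers_motif = _motifs_for(genome, snp_hash, rec.chrom,
                                            rec.donor_pos0, rec.acceptor_pos0)
        out[key] = JunctionRecord(rec.chrom, rec.donor_pos0, rec.acceptor_pos0,
                                  rec.strand, ref_motif, pers_motif, rec.support,
                                  classify_motifs(ref_motif, pers_motif))
    return out


def coverage_change_table(catalogs: dict, genotypes: dict, genome: Genome,
                          direction: str):
    """Cohort coverage-change matrix for polymorphic junctions.

    catalogs:  {individual: junction catalog}; genotypes: {individual: SnpHash}.
    direction: 'gain' or 'loss'. For every junction classified in the given
    direction under at least one individual's alleles, read support is
    averaged separately over carriers (individuals whose alleles change the
    motif in that direction) and non-carriers, zero-support individuals
    included. The matrix cell [non-carrier bin, carrier bin] is incremented,
    with bins 0, (0,2], (2,10], (10,+inf). Junctions with no carrier or no
    non-carrier individuals are skipped and counted separately.

    Returns (matrix 4x4 ndarray, skipped count).
    """
    if not catalogs:
        raise ValueError("empty cohort")
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    individuals = sorted(catalogs)
    union_keys = sorted({k for cat in catalogs.values() for k in cat})
    matrix = np.zeros((4, 4), dtype=int)
    skipped = 0
    for key in union_keys:
        chrom, donor0, acceptor0, _ = key
        carriers, noncarriers = [], []
        is_direction = False
        for ind in individuals:
            ref_motif, pers_motif = _motifs_for(genome, genotypes[ind], chrom,
                                                donor0, acceptor0)
            if classify_motifs(ref_motif, pers_motif) == direction:
                carriers.append(ind)
                is_direction = True
            else:
                noncarriers.append(ind)
        if not is_direction:
            continue
        if not carriers or not noncarriers:
            skipped += 1
            continue
        support = {ind: catalogs[ind].get(key).support if key in catalogs[ind] else 0
                   for ind in individuals}
        carrier_avg = float(np.mean([support[i] for i in carriers]))
        noncarrier_avg = float(np.mean([support[i] for i in noncarriers]))
        matrix[_coverage_bin(noncarrier_avg), _coverage_bin(carrier_avg)] += 1
    return matrix, skipped


def filter_by_support(catalogs: dict, genome: Genome, genotypes: dict,
                      min_reads: int, min_individuals: int) -> int:
    """Count gain junctions supported by >= min_reads reads in >= min_individuals
    individuals (support counted only in individuals carrying the gain allele)."""
    union_keys = sorted({k for cat in catalogs.values() for k in cat})
    count = 0
    for key in union_keys:
        chrom, donor0, acceptor0, _ = key
        n_supporting = 0
        for ind, cat in catalogs.items():
            ref_motif, pers_motif = _motifs_for(genome, genotypes[ind], chrom,
                                                donor0, acceptor0)
            if classify_motifs(ref_motif, pers_motif) != "gain":
                continue
            rec = cat.get(key)
            if rec is not None and rec.support >= min_reads:
                n_supporting += 1
        if n_supporting >= min_individuals:
            count += 1
    return count


def support_grid(catalogs: dict, genome: Genome, genotypes: dict,
                 read_thresholds=(2, 5, 10),
                 individual_thresholds=(1, 2, 5, 10)) -> pd.DataFrame:
    """Grid of gain-junction counts over read/individual support thresholds."""
    data = {
        f">={r}": [filter_by_support(catalogs, genome, genotypes, r, i)
                   for i in individual_thresholds]
        for r in read_thresholds
    }
    return pd.DataFrame(data, index=[f">={i}" for i in individual_thresholds])
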