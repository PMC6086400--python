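"""Per-SNP reference allelic ratios and distribution bias summaries.

At a heterozygous SNP the reference allelic ratio is refCount /
(refCount + altCount) over uniquely aligned reads covering the site. Reads
drawn equally from both haplotypes should center this at 0.5; systematic
excess above 0.5 is the signature of reference bias. The distribution over
SNPs is summarized by its mean and (biased, g1) sample skewness over sites
with at least `min_reads` allele-informative reads.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import revcomp

__all__ = [
    "AllelicCounts",
    "RatioSummary",
    "count_alleles",
    "count_alleles_from_sam",
    "summarize_ratio_distribution",
    "ratio_histogram",
]


@dataclass
class AllelicCounts:
    snp: object  # SnpVariant
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0

    @property
    def ratio(self) -> float | None:
        denom = self.ref_count + self.alt_count
        return self.ref_count / denom if denom else None


@dataclass(frozen=True)
class RatioSummary:
    n_snps_covered: int
    mean: float  # nan when no SNP passes the filter
    skewness: float


def _tally(counter: AllelicCounts, base: str) -> None:
    if base == counter.snp.ref:
        counter.ref_count += 1
    elif base == counter.snp.alt:
        counter.alt_count += 1
    else:
        counter.other_count += 1


def count_alleles(results, snps, reads) -> list[AllelicCounts]:
    """Tally aligned read bases at SNP positions.

    results: {read id: [SplicedAlignment, ...]}; only uniquely mapped reads
    (exactly one reported alignment) contribute. Soft-clipped bases never
    count, and a spliced read whose intron spans the SNP does not cover it.
    """
    counters = {(s.chrom, s.pos0): AllelicCounts(s) for s in snps}
    by_chrom: dict[str, list[int]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s.pos0)
    for positions in by_chrom.values():
        positions.sort()
    for read_id, alns in results.items():
        if len(alns) != 1:
            continue
        aln = alns[0]
        positions = by_chrom.get(aln.chrom)
        if not positions:
            continue
        read = reads[read_id]
        oriented = read.seq if aln.orientation == "forward" else revcomp(read.seq)
        for blk in aln.blocks:
            i = bisect_left(positions, blk.ref_start)
            while i < len(positions) and positions[i] < blk.ref_start + blk.length:
                pos = positions[i]
                base = oriented[blk.read_start + pos - blk.ref_start]
                _tally(counters[(aln.chrom, pos)], base)
                i += 1
    return [counters[(s.chrom, s.pos0)] for s in sorted(snps)]


def count_alleles_from_sam(sam_path, snps) -> list[AllelicCounts]:
    """Same tally computed from a SAM file written by this package.

    Uniqueness uses the NH tag (NH == 1); secondary and unmapped records are
    skipped. Aligned pairs come from the CIGAR, so soft clips and introns are
    excluded exactly as in count_alleles.
    """
    import pysam

    counters = {(s.chrom, s.pos0): AllelicCounts(s) for s in snps}
    lookup: dict[str, dict[int, AllelicCounts]] = {}
    for s in snps:
        lookup.setdefault(s.chrom, {})[s.pos0] = counters[(s.chrom, s.pos0)]
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("NH") and rec.get_tag("NH") != 1:
                continue
            chrom_map = lookup.get(rec.reference_name)
            if not chrom_map:
                continue
            seq = rec.query_sequence
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                counter = chrom_map.get(rpos)
                if counter is not None:
                    _tally(counter, seq[qpos])
    return [counters[(s.chrom, s.pos0)] for s in sorted(snps)]


def summarize_ratio_distribution(counts, min_reads: int = 10) -> RatioSummary:
    """Mean and g1 sample skewness of ratios over SNPs with enough coverage."""
    ratios = [c.ratio for c in counts
              if c.ref_count + c.alt_count >= min_reads]
    if not ratios:
        return RatioSummary(0, math.nan, math.nan)
    arr = np.asarray(ratios, dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        skew = 0.0  # a constant sample is symmetric; g1 would be 0/0
    else:
        skew = float(stats.skew(arr, bias=True))
    return RatioSummary(len(ratios), float(arr.mean()), skew)


def ratio_histogram(counts, min_reads: int = 10, bins: int = 20):
    """Histogram of ratios over [0, 1]; returns (bin_edges, counts)."""
    ratios = [c.ratio for c in counts
              if c.ref_count + c.alt_count >= min_reads]
    hist, edges = np.histogram(ratios, bins=bins, range=(0.0, 1.0))
    return edges, hist
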