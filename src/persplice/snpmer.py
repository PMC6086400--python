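"""SNP-mer extraction.

A SNP-mer is a window of genomic sequence carrying a SNP's alternate allele,
with the SNP localized to the middle of the window. Indexed alongside the
reference genome, SNP-mers let reads that carry alternate alleles find exact
matches, removing the mismatch penalty that causes reference bias.

Two schemes are implemented:

* phased -- fixed-length windows (201 bp by default) cut from each of the two
  haplotypes, with every haplotype SNP inside the window substituted, so each
  window is a literal haplotype substring.
* unphased -- variable-length windows driven by the distance d to the nearest
  neighbouring SNP on the same contig: d > k_max gives a k_max window with only
  the central substitution; k_min <= d <= k_max gives a window of length d;
  d < k_min marks a SNP-rich region, where the 2^(n-1) alternate/reference
  combinations of the n-1 non-central SNPs inside a k_min window are sampled
  (m windows per SNP, without replacement, seeded).
"""

from __future__ import annotations

import zlib
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord, SnpVariant

__all__ = [
    "SnpMer",
    "SnpMerParams",
    "extract_phased_snpmers",
    "extract_unphased_snpmers",
    "snpmer_to_reference",
    "snpmers_to_fasta_records",
]


@dataclass(frozen=True)
class SnpMerParams:
    """Window-length and sampling parameters for SNP-mer extraction.

    k_phased: fixed phased window length, odd (default 201 bp).
    k_max / k_min: unphased window bounds (defaults 201 / 31 bp).
    m: combinations sampled per SNP in SNP-rich regions (default 4).
    """

    k_phased: int = 201
    k_max: int = 201
    k_min: int = 31
    m: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.k_phased % 2 == 0 or self.k_phased < 3:
            raise ValueError("k_phased must be an odd integer >= 3")
        if not (self.k_max >= self.k_min >= 3):
            raise ValueError("require k_max >= k_min >= 3")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass(frozen=True)
class SnpMer:
    """An alternate-allele window with provenance.

    seq differs from the reference substring [ref_start0, ref_start0+len(seq))
    exactly at the embedded SNP offsets. embedded is a tuple of
    (offset_in_seq, SnpVariant) for every substituted SNP, central included.
    """

    seq: str
    chrom: str
    ref_start0: int
    central: SnpVariant
    embedded: tuple = ()
    haplotype: str = "na"

    @property
    def central_offset(self) -> int:
        return self.central.pos0 - self.ref_start0

    def fasta_name(self) -> str:
        return f"{self.chrom}:{self.ref_start0}:{self.central.pos0}:{self.haplotype}"


def _window(pos: int, k: int, contig_len: int) -> tuple[int, int]:
    """Window of length k centered on pos (offset floor((k-1)/2)), truncated
    at contig ends without padding."""
    lo = max(0, pos - (k - 1) // 2)
    hi = min(contig_len, pos - (k - 1) // 2 + k)
    return lo, hi


def _substitute(ref_window: str, lo: int, snps) -> tuple[str, tuple]:
    chars = list(ref_window)
    embedded = []
    for s in snps:
        off = s.pos0 - lo
        chars[off] = s.alt
        embedded.append((off, s))
    return "".join(chars), tuple(sorted(embedded))


def _dedup(mers: list[SnpMer]) -> list[SnpMer]:
    """Drop byte-identical windows; haplotype-mirrored duplicates collapse to 'na'."""
    seen: dict[tuple, SnpMer] = {}
    for mer in mers:
        key = (mer.chrom, mer.ref_start0, mer.seq)
        prev = seen.get(key)
        if prev is None:
            seen[key] = mer
        elif prev.haplotype != mer.haplotype:
            seen[key] = SnpMer(prev.seq, prev.chrom, prev.ref_start0,
                               prev.central, prev.embedded, "na")
    return sorted(seen.values(), key=lambda m: (m.chrom, m.ref_start0, m.haplotype, m.seq))


def extract_phased_snpmers(genome, snps, params: SnpMerParams | None = None) -> list[SnpMer]:
    """One fixed-length window per (haplotype, SNP), a literal haplotype substring.

    Every SNP must be phased ('hap1', 'hap2' or 'both'). All other SNPs of the
    same haplotype falling inside a window are substituted along with the
    central one. Homozygous-alternate SNPs yield identical windows on both
    haplotypes, which deduplicate to one window with haplotype 'na'.
    """
    params = params or SnpMerParams()
    contig_len = {r.name: len(r.seq) for r in genome}
    contig_seq = {r.name: r.seq for r in genome}
    for s in snps:
        if s.phase not in ("hap1", "hap2", "both"):
            raise ValueError(
                f"SNP {s.chrom}:{s.pos0 + 1} is unphased; use extract_unphased_snpmers "
                "for unphased genotype data"
            )
    mers: list[SnpMer] = []
    for hap in ("hap1", "hap2"):
        hap_snps = [s for s in snps if s.phase in (hap, "both")]
        by_chrom: dict[str, list[SnpVariant]] = {}
        for s in hap_snps:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, chrom_snps in by_chrom.items():
            chrom_snps.sort(key=lambda s: s.pos0)
            positions = [s.pos0 for s in chrom_snps]
            clen = contig_len[chrom]
            for s in chrom_snps:
                lo, hi = _window(s.pos0, params.k_phased, clen)
                i0 = bisect_left(positions, lo)
                i1 = bisect_right(positions, hi - 1)
                inside = chrom_snps[i0:i1]
                seq, embedded = _substitute(contig_seq[chrom][lo:hi], lo, inside)
                mers.append(SnpMer(seq, chrom, lo, s, embedded, hap))
    return _dedup(mers)


def _rich_rng(params: SnpMerParams, chrom: str, pos0: int) -> np.random.Generator:
    # Per-SNP stream so sampling is order-independent and seed-stable.
    tag = zlib.crc32(chrom.encode()) ^ pos0
    return np.random.default_rng(np.random.SeedSequence([params.seed, tag]))


def extract_unphased_snpmers(genome, snps, params: SnpMerParams | None = None) -> list[SnpMer]:
    """Variable-length windows following the three nearest-neighbour scenarios."""
    params = params or SnpMerParams()
    contig_len = {r.name: len(r.seq) for r in genome}
    contig_seq = {r.name: r.seq for r in genome}
    by_chrom: dict[str, list[SnpVariant]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    mers: list[SnpMer] = []
    for chrom, chrom_snps in by_chrom.items():
        chrom_snps.sort(key=lambda s: s.pos0)
        positions = [s.pos0 for s in chrom_snps]
        clen = contig_len[chrom]
        cseq = contig_seq[chrom]
        for i, s in enumerate(chrom_snps):
            dists = []
            if i > 0:
                dists.append(s.pos0 - positions[i - 1])
            if i + 1 < len(chrom_snps):
                dists.append(positions[i + 1] - s.pos0)
            d = min(dists) if dists else None  # None: no neighbour => d = infinity
            if d is None or d > params.k_max:
                lo, hi = _window(s.pos0, params.k_max, clen)
                seq, embedded = _substitute(cseq[lo:hi], lo, [s])
                mers.append(SnpMer(seq, chrom, lo, s, embedded, "na"))
            elif d >= params.k_min:
                lo, hi = _window(s.pos0, d, clen)
                seq, embedded = _substitute(cseq[lo:hi], lo, [s])
                mers.append(SnpMer(seq, chrom, lo, s, embedded, "na"))
            else:
                lo, hi = _window(s.pos0, params.k_min, clen)
                i0 = bisect_left(positions, lo)
                i1 = bisect_right(positions, hi - 1)
                others = [t for t in chrom_snps[i0:i1] if t.pos0 != s.pos0]
                n_other = len(others)
                total = 1 << n_other
                count = min(params.m, total)
                rng = _rich_rng(params, chrom, s.pos0)
                if total <= (1 << 20):
                    masks = rng.choice(total, size=count, replace=False)
                else:  # sample distinct masks lazily when enumeration is infeasible
                    picked: set[int] = set()
                    while len(picked) < count:
                        picked.add(int(rng.integers(total)))
                    masks = sorted(picked)
                for mask in sorted(int(m) for m in masks):
                    chosen = [s] + [o for b, o in enumerate(others) if mask >> b & 1]
                    seq, embedded = _substitute(cseq[lo:hi], lo, chosen)
                    mers.append(SnpMer(seq, chrom, lo, s, embedded, "na"))
    return _dedup(mers)


def snpmer_to_reference(mer: SnpMer, offset: int, length: int):
    """Convert a match inside a SNP-mer to reference coordinates.

    Returns (chrom, ref_start0, covered) where covered is the tuple of embedded
    SNPs whose offsets fall inside [offset, offset+length).
    """
    if offset < 0 or length < 0 or offset + length > len(mer.seq):
        raise ValueError(
            f"hit [{offset}, {offset + length}) outside SNP-mer of length {len(mer.seq)}"
        )
    covered = tuple(s for off, s in mer.embedded if offset <= off < offset + length)
    return mer.chrom, mer.ref_start0 + offset, covered


def snpmers_to_fasta_records(mers) -> list[SequenceRecord]:
    """Serialize SNP-mers as plain sequences with structured headers."""
    return [SequenceRecord(m.fasta_name(), m.seq) for m in mers]
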