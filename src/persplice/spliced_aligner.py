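"""SNP-aware spliced alignment.

Seed hits from the index are merged into exonic segments, segments separated
on the genome are bridged by *double-anchor spliced alignment* (both sides of
the putative intron are anchored by an exact seed), candidate alignments are
assembled, and the best-scoring candidates are reported. Two SNP-aware moves
distinguish the method from plain reference alignment:

* mismatches explainable by the individual's SNPs (read base equals the
  alternate allele) are removed from the mismatch count before scoring, and
* candidate splice sites are evaluated under both reference and alternate
  alleles, so a SNP that creates a canonical donor/acceptor dinucleotide can
  complete a spliced alignment the reference sequence alone would reject.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np

from ._seq import Genome, encode_query, revcomp
from .genome_index import PrefixHit, SeqIndex, iterative_segment_search
from .io_formats import JunctionRecord, ReadRecord, SnpVariant
from .motifs import (CANONICAL_PAIRS, PRIMARY_PAIRS, SIDE_MOTIFS,
                     classify_motifs, is_canonical, pair_strand)

__all__ = [
    "AlignParams",
    "SnpHash",
    "Segment",
    "Block",
    "SplicedAlignment",
    "merge_adjacent_segments",
    "candidate_splice_sites",
    "double_anchor_splice",
    "assemble_and_score",
    "align_read",
    "align_reads",
]

Block = namedtuple("Block", "ref_start length read_start")


@dataclass(frozen=True)
class AlignParams:
    """Alignment tunables.

    min_match: minimum seed length returned by the prefix search (30 bp).
    seed_min: seeds shorter than this are discarded outright (18 bp).
    min_anchor: exact-match bases required on each side of a junction, also
        the number of anchor bases a split point may re-assign (8 bp).
    min_intron / max_intron: acceptable intron span (20 / 200,000 bp).
    max_mismatch_rate: per-read mismatch budget, ceil(len * rate), applied to
        the SNP-excluded count (default 1/25).
    w_mism / w_junc / w_noncanon: scoring weights; score = mapped length
        - w_mism * SNP-excluded mismatches - w_junc * junctions
        - w_noncanon * noncanonical junctions.
    """

    min_match: int = 30
    seed_min: int = 18
    min_anchor: int = 8
    min_intron: int = 20
    max_intron: int = 200_000
    max_mismatch_rate: float = 1.0 / 25.0
    w_mism: int = 2
    w_junc: int = 1
    w_noncanon: int = 4
    max_merge_gap: int = 2
    max_bridge_read_gap: int = 12
    min_mapped_frac: float = 0.5
    use_kmer_screen: bool = True

    def max_mismatches(self, read_len: int) -> int:
        return math.ceil(read_len * self.max_mismatch_rate)


class SnpHash:
    """Hash of an individual's SNPs keyed by (chrom, pos0), with range queries."""

    def __init__(self, snps=()):
        self._map: dict[tuple[str, int], SnpVariant] = {}
        by_chrom: dict[str, list[SnpVariant]] = {}
        for s in snps:
            key = (s.chrom, s.pos0)
            if key in self._map:
                raise ValueError(f"duplicate SNP at {s.chrom}:{s.pos0 + 1}")
            self._map[key] = s
            by_chrom.setdefault(s.chrom, []).append(s)
        self._sorted: dict[str, tuple[list[int], list[SnpVariant]]] = {}
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda s: s.pos0)
            self._sorted[chrom] = ([s.pos0 for s in lst], lst)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, key) -> bool:
        return key in self._map

    def get(self, chrom: str, pos0: int) -> SnpVariant | None:
        return self._map.get((chrom, pos0))

    def snps(self):
        return sorted(self._map.values())

    def in_range(self, chrom: str, start: int, end: int):
        """Yield (snp, offset_from_start) for SNPs with start <= pos0 < end."""
        entry = self._sorted.get(chrom)
        if entry is None:
            return
        positions, lst = entry
        i0 = bisect_left(positions, start)
        i1 = bisect_left(positions, end)
        for i in range(i0, i1):
            yield lst[i], positions[i] - start

    def personal_dinuc(self, genome: Genome, chrom: str, pos0: int) -> tuple[str, str]:
        """(reference, personalized) dinucleotide at [pos0, pos0+2)."""
        ref = genome.seq[chrom][pos0:pos0 + 2]
        chars = list(ref)
        for i in range(len(chars)):
            snp = self.get(chrom, pos0 + i)
            if snp is not None:
                chars[i] = snp.alt
        return ref, "".join(chars)


@dataclass(frozen=True)
class Segment:
    """A maximal exact (up to re-verified small gaps) read-to-genome segment."""

    chrom: str
    diag: int  # ref_start - read_start, constant along the segment
    read_start: int
    read_end: int
    snps: tuple = ()
    from_snpmer: bool = False

    @property
    def ref_start(self) -> int:
        return self.read_start + self.diag

    @property
    def ref_end(self) -> int:
        return self.read_end + self.diag


@dataclass(frozen=True)
class Bridge:
    """The resolved split of a double-anchor spliced alignment."""

    split: int  # read offset where the acceptor-side exon resumes
    donor_pos0: int
    acceptor_pos0: int
    ref_motif: str
    pers_motif: str
    strand: str
    noncanonical: bool
    polymorphic: str
    cost: int  # SNP-excluded mismatches inside the bridged window


@dataclass(frozen=True)
class SplicedAlignment:
    """A final alignment: ordered exonic blocks, junctions, score."""

    read_id: str
    chrom: str
    orientation: str  # 'forward' | 'revcomp'
    blocks: tuple  # of Block, oriented-read coordinates
    junctions: tuple  # of JunctionRecord
    mism_raw: int
    mism_snp_excluded: int
    soft_clip5: int
    soft_clip3: int
    score: int
    origin: str = "reference"  # 'snpmer' when any seed came from a SNP-mer

    @property
    def mapped_length(self) -> int:
        return sum(b.length for b in self.blocks)


# ---------------------------------------------------------------------------
# Step 2a: merge adjacent segments


def merge_adjacent_segments(hits, params: AlignParams | None = None) -> list[Segment]:
    """Fuse hits that are contiguous in both read and reference.

    Hits sharing a diagonal (identical read-to-reference offset) whose read
    intervals overlap or leave a gap of at most max_merge_gap bases are fused;
    the gap bases are re-verified against the genome when mismatches are
    recounted at scoring time. Hits on different diagonals stay separate and
    become candidate junction anchors.
    """
    params = params or AlignParams()
    groups: dict[tuple[str, int], list[PrefixHit]] = {}
    for h in hits:
        groups.setdefault((h.chrom, h.diag), []).append(h)
    segments: list[Segment] = []
    for (chrom, diag), ghits in groups.items():
        intervals = sorted(((h.query_offset, h.query_offset + h.length, h) for h in ghits),
                           key=lambda t: t[:2])
        cur_s, cur_e, h0 = intervals[0]
        cur_snps = set(h0.snps)
        cur_mer = h0.origin == "snpmer"
        for s, e, h in intervals[1:]:
            if s - cur_e <= params.max_merge_gap:
                cur_e = max(cur_e, e)
                cur_snps.update(h.snps)
                cur_mer = cur_mer or h.origin == "snpmer"
            else:
                segments.append(Segment(chrom, diag, cur_s, cur_e,
                                        tuple(sorted(cur_snps)), cur_mer))
                cur_s, cur_e = s, e
                cur_snps = set(h.snps)
                cur_mer = h.origin == "snpmer"
        segments.append(Segment(chrom, diag, cur_s, cur_e,
                                tuple(sorted(cur_snps)), cur_mer))
    segments.sort(key=lambda s: (s.read_start, s.read_end, s.chrom, s.diag))
    return segments


# ---------------------------------------------------------------------------
# Step 2b: candidate splice sites under personal alleles


def candidate_splice_sites(genome: Genome, chrom: str, start: int, end: int,
                           snp_hash: SnpHash, side: str, strand: str):
    """Scan [start, end) for dinucleotides that are a canonical donor/acceptor
    side under the personalized alleles.

    Returns [(pos0, personalized_motif, polymorphic), ...] where polymorphic
    is True iff the reference dinucleotide is noncanonical for this side but
    the SNP-substituted one is canonical.
    """
    motifs = SIDE_MOTIFS[(side, strand)]
    out = []
    for pos in range(max(0, start), min(end, genome.length(chrom)) - 1):
        ref, pers = snp_hash.personal_dinuc(genome, chrom, pos)
        if pers in motifs:
            out.append((pos, pers, ref not in motifs))
        elif ref in motifs:
            # canonical under the reference but destroyed by a personal
            # allele: still a reference candidate; the loss is recorded
            # downstream by junction classification.
            out.append((pos, ref, False))
    return out


# ---------------------------------------------------------------------------
# Step 2c: double-anchor spliced alignment


def _mism_indicator(genc, read_enc, oriented_seq, chrom, snp_hash,
                    r0: int, r1: int, diag: int) -> np.ndarray:
    """SNP-excluded mismatch indicator for read positions [r0, r1) on a diagonal."""
    if r1 <= r0:
        return np.zeros(0, dtype=np.int64)
    g = genc[r0 + diag:r1 + diag]
    r = read_enc[r0:r1]
    mm = (g != r).astype(np.int64)
    if len(snp_hash):
        for off in np.nonzero(mm)[0].tolist():
            snp = snp_hash.get(chrom, r0 + off + diag)
            if snp is not None and oriented_seq[r0 + off] == snp.alt:
                mm[off] = 0
    return mm


def _junction_class(refD, refA, persD, persA) -> int:
    """Tie-break class: 0 reference GT-AG, 1 polymorphic GT-AG, 2 other
    canonical, 3 noncanonical."""
    combos = {(d, a) for d in (refD, persD) for a in (refA, persA)}
    if (refD, refA) in PRIMARY_PAIRS:
        return 0
    if combos & PRIMARY_PAIRS:
        return 1
    if combos & CANONICAL_PAIRS:
        return 2
    return 3


def _junction_strand(refD, refA, persD, persA) -> str:
    combos = sorted({(d, a) for d in (refD, persD) for a in (refA, persA)})
    for pool in (PRIMARY_PAIRS, CANONICAL_PAIRS):
        for pair in combos:
            if pair in pool:
                return pair_strand(*pair)
    return "+"


def double_anchor_splice(left: Segment, right: Segment, read_enc: np.ndarray,
                         oriented_seq: str, genome: Genome, snp_hash: SnpHash,
                         params: AlignParams | None = None) -> list[Bridge]:
    """Bridge two anchored segments across a putative intron.

    Split points are enumerated over the unaligned read interval plus up to
    min_anchor bases of re-assignable anchor overlap. Splits whose
    donor/acceptor dinucleotides are canonical under the reference or the
    personal alleles are preferred; among those, SNP-excluded mismatches are
    minimized, ties broken by reference GT-AG, then polymorphic GT-AG, then
    other canonical motifs, then the leftmost donor. When no canonical split
    exists, the best noncanonical split is returned and carries the
    noncanonical scoring penalty.
    """
    params = params or AlignParams()
    if left.chrom != right.chrom:
        return []
    chrom = left.chrom
    dL, dR = left.diag, right.diag
    intron = dR - dL
    if not (params.min_intron <= intron <= params.max_intron):
        return []
    clen = genome.length(chrom)
    lo = max(left.read_start + 1, left.read_end - params.min_anchor)
    hi = min(right.read_end - 1, right.read_start + params.min_anchor)
    # keep both intron-end dinucleotides inside the contig
    lo = max(lo, -dL, 2 - dR)
    hi = min(hi, clen - dL - 2, clen - dR)
    if lo > hi:
        return []
    genc = genome.enc[chrom]
    seq = genome.seq[chrom]
    w0 = min(lo, left.read_end)
    w1 = max(hi, right.read_start)
    mmL = _mism_indicator(genc, read_enc, oriented_seq, chrom, snp_hash, w0, w1, dL)
    mmR = _mism_indicator(genc, read_enc, oriented_seq, chrom, snp_hash, w0, w1, dR)
    cumL = np.concatenate([[0], np.cumsum(mmL)])
    cumR = np.concatenate([[0], np.cumsum(mmR)])
    totalR = int(cumR[-1])

    best = None
    for s in range(lo, hi + 1):
        cost = int(cumL[s - w0]) + totalR - int(cumR[s - w0])
        refD = seq[s + dL:s + dL + 2]
        refA = seq[s + dR - 2:s + dR]
        _, persD = snp_hash.personal_dinuc(genome, chrom, s + dL)
        _, persA = snp_hash.personal_dinuc(genome, chrom, s + dR - 2)
        cls = _junction_class(refD, refA, persD, persA)
        key = (cost, cls, s)
        if best is None or key < best[0]:
            best = (key, refD, refA, persD, persA)
    (cost, cls, s), refD, refA, persD, persA = best
    return [Bridge(
        split=s,
        donor_pos0=s + dL,
        acceptor_pos0=s + dR - 1,
        ref_motif=refD + refA,
        pers_motif=persD + persA,
        strand=_junction_strand(refD, refA, persD, persA),
        noncanonical=cls == 3,
        polymorphic=classify_motifs(refD + refA, persD + persA),
        cost=cost,
    )]


# ---------------------------------------------------------------------------
# Step 3: assembly and scoring


def _count_mismatches(blocks, chrom, read_enc, oriented_seq, genome, snp_hash):
    """(raw, SNP-excluded) mismatch counts over the aligned blocks.

    A mismatch is SNP-attributable iff the reference position is in the hash
    and the read base equals that SNP's alternate allele. When the hash
    carries phase information, attribution additionally requires the read's
    alleles over all covered phased SNPs to be consistent with a single
    haplotype; inconsistent phased mismatches stay counted.
    """
    genc = genome.enc[chrom]
    raw = 0
    attributable: list[SnpVariant] = []
    covered_phased: list[tuple[SnpVariant, str]] = []
    for blk in blocks:
        g = genc[blk.ref_start:blk.ref_start + blk.length]
        r = read_enc[blk.read_start:blk.read_start + blk.length]
        neq = np.nonzero(g != r)[0]
        raw += len(neq)
        if not len(snp_hash):
            continue
        mism_offs = set(neq.tolist())
        for snp, off in snp_hash.in_range(chrom, blk.ref_start, blk.ref_start + blk.length):
            read_base = oriented_seq[blk.read_start + off]
            if snp.phase in ("hap1", "hap2"):
                covered_phased.append((snp, read_base))
            if off in mism_offs and read_base == snp.alt:
                attributable.append(snp)
    if not attributable:
        return raw, raw
    if any(s.phase in ("hap1", "hap2") for s in attributable):
        ok_hap = None
        for hap in ("hap1", "hap2"):
            consistent = True
            for snp, base in covered_phased:
                expect = snp.alt if snp.phase in (hap, "both") else snp.ref
                if base in (snp.ref, snp.alt) and base != expect:
                    consistent = False
                    break
            if consistent:
                ok_hap = hap
                break
        if ok_hap is None:
            excluded = [s for s in attributable if s.phase in ("both", "unphased")]
        else:
            excluded = [s for s in attributable
                        if s.phase in (ok_hap, "both", "unphased")]
    else:
        excluded = attributable
    return raw, raw - len(excluded)


def _best_extension(base: int, limit: int, step: int, diag: int, chrom: str,
                    read_enc, oriented_seq, genome, snp_hash, w_mism: int) -> int:
    """Optimal clip point for an unanchored read tail.

    Extends the terminal block from read position `base` towards `limit`
    (step -1 for the 5' tail, +1 for the 3' tail), maximizing
    extension_length - w_mism * mismatches with SNP-attributable mismatches
    not charged; ties prefer the shorter extension. Returns the new boundary.
    """
    if base == limit:
        return base
    genc = genome.enc[chrom]
    if step < 0:
        mm = _mism_indicator(genc, read_enc, oriented_seq, chrom, snp_hash,
                             limit, base, diag)
        best_x, best_val, k = base, 0, 0
        for x in range(base - 1, limit - 1, -1):
            k += int(mm[x - limit])
            val = (base - x) - w_mism * k
            if val > best_val:
                best_val, best_x = val, x
        return best_x
    mm = _mism_indicator(genc, read_enc, oriented_seq, chrom, snp_hash,
                         base, limit, diag)
    best_x, best_val, k = base, 0, 0
    for x in range(base + 1, limit + 1):
        k += int(mm[x - base - 1])
        val = (x - base) - w_mism * k
        if val > best_val:
            best_val, best_x = val, x
    return best_x


def _finalize(path_segs, bridges, read_id, oriented_seq, read_enc, genome,
              snp_hash, params, orientation) -> SplicedAlignment | None:
    chrom = path_segs[0].chrom
    n_read = len(oriented_seq)
    clen = genome.length(chrom)
    bounds = [path_segs[0].read_start] + [b.split for b in bridges] + [path_segs[-1].read_end]
    diags = [s.diag for s in path_segs]
    for k in range(len(bounds) - 1):
        if bounds[k + 1] <= bounds[k]:
            return None
    d_first, d_last = diags[0], diags[-1]
    start = _best_extension(bounds[0], max(0, -d_first), -1, d_first, chrom,
                            read_enc, oriented_seq, genome, snp_hash, params.w_mism)
    end = _best_extension(bounds[-1], min(n_read, clen - d_last), +1, d_last, chrom,
                          read_enc, oriented_seq, genome, snp_hash, params.w_mism)
    bounds[0], bounds[-1] = start, end
    blocks = tuple(
        Block(bounds[k] + diags[k], bounds[k + 1] - bounds[k], bounds[k])
        for k in range(len(diags))
    )
    raw, excl = _count_mismatches(blocks, chrom, read_enc, oriented_seq,
                                  genome, snp_hash)
    mapped = end - start
    n_noncanon = sum(1 for b in bridges if b.noncanonical)
    score = (mapped - params.w_mism * excl - params.w_junc * len(bridges)
             - params.w_noncanon * n_noncanon)
    if excl > params.max_mismatches(n_read):
        return None
    if mapped * 2 < n_read:
        return None
    junctions = tuple(
        JunctionRecord(chrom, b.donor_pos0, b.acceptor_pos0, b.strand,
                       b.ref_motif, b.pers_motif, 0, b.polymorphic)
        for b in bridges
    )
    origin = "snpmer" if any(s.from_snpmer for s in path_segs) else "reference"
    return SplicedAlignment(read_id, chrom, orientation, blocks, junctions,
                            raw, excl, start, n_read - end, score, origin)


def assemble_and_score(segments, read_id: str, oriented_seq: str,
                       read_enc: np.ndarray, genome: Genome, snp_hash: SnpHash,
                       params: AlignParams | None = None,
                       orientation: str = "forward") -> list[SplicedAlignment]:
    """Assemble candidate alignments from merged segments and spliced bridges.

    Candidates are consistent chains of segments (bridged where separated on
    the genome, soft-clipped or extended at the tails), scored as
    mapped_length - w_mism * SNP-excluded mismatches - w_junc * junctions
    - w_noncanon * noncanonical junctions. All candidates achieving the
    maximum score are returned; candidates exceeding the mismatch budget or
    mapping less than half the read are dropped.
    """
    params = params or AlignParams()
    if not segments:
        return []
    segs = list(segments)
    n = len(segs)
    succ: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        si = segs[i]
        cand = []
        for j in range(n):
            if i == j:
                continue
            sj = segs[j]
            if sj.chrom != si.chrom or sj.diag <= si.diag:
                continue
            if sj.read_start <= si.read_start or sj.read_end <= si.read_end:
                continue
            gap = sj.read_start - si.read_end
            if gap > params.max_bridge_read_gap or gap < -params.min_anchor:
                continue
            intron = sj.diag - si.diag
            if not (params.min_intron <= intron <= params.max_intron):
                continue
            cand.append((abs(gap), intron, j))
        cand.sort()
        succ[i] = [j for _, _, j in cand[:4]]

    paths: list[list[int]] = []

    def dfs(path: list[int]) -> None:
        paths.append(list(path))
        if len(path) >= 4 or len(paths) >= 256:
            return
        for j in succ[path[-1]]:
            dfs(path + [j])

    for i in range(n):
        if len(paths) < 256:
            dfs([i])

    bridge_cache: dict[tuple[int, int], Bridge | None] = {}
    candidates: list[SplicedAlignment] = []
    seen = set()
    for path in paths:
        bridges = []
        ok = True
        for u, v in zip(path, path[1:]):
            if (u, v) not in bridge_cache:
                found = double_anchor_splice(segs[u], segs[v], read_enc,
                                             oriented_seq, genome, snp_hash, params)
                bridge_cache[(u, v)] = found[0] if found else None
            br = bridge_cache[(u, v)]
            if br is None:
                ok = False
                break
            bridges.append(br)
        if not ok:
            continue
        aln = _finalize([segs[k] for k in path], bridges, read_id, oriented_seq,
                        read_enc, genome, snp_hash, params, orientation)
        if aln is None:
            continue
        key = (aln.chrom, aln.blocks)
        if key not in seen:
            seen.add(key)
            candidates.append(aln)
    if not candidates:
        return []
    best = max(a.score for a in candidates)
    out = [a for a in candidates if a.score == best]
    out.sort(key=lambda a: (a.chrom, a.blocks[0].ref_start))
    return out


# ---------------------------------------------------------------------------
# The whole pipeline for one read


def align_read(index: SeqIndex, read: ReadRecord, genome: Genome,
               snp_hash: SnpHash | None = None,
               params: AlignParams | None = None) -> list[SplicedAlignment]:
    """Align one read: iterative segment search, merging, bridging, scoring.

    Both the read and its reverse complement are tried; the better-scoring
    orientation wins, with ties reported from both. An empty list means
    unmapped (including reads shorter than the seed length).
    """
    params = params or AlignParams()
    snp_hash = snp_hash if snp_hash is not None else SnpHash()
    n = len(read.seq)
    if n < params.min_match:
        return []
    results: list[SplicedAlignment] = []
    for orientation in ("forward", "revcomp"):
        seq = read.seq if orientation == "forward" else revcomp(read.seq)
        qenc = encode_query(seq)
        screened = (params.use_kmer_screen and params.min_match >= 30
                    and not index.has_seed_kmer(qenc))
        if screened:
            cands = []
        else:
            hits = iterative_segment_search(index, seq, min_len=params.min_match,
                                            seed_min=params.seed_min)
            segs = merge_adjacent_segments(hits, params)
            cands = assemble_and_score(segs, read.id, seq, qenc, genome,
                                       snp_hash, params, orientation)
        results.extend(cands)
        # a perfect full-length exonic forward match cannot be beaten
        if orientation == "forward" and cands and cands[0].score >= n:
            break
    if not results:
        return []
    best = max(a.score for a in results)
    out = [a for a in results if a.score == best]
    out.sort(key=lambda a: (a.chrom, a.blocks[0].ref_start, a.orientation))
    return out


def align_reads(index: SeqIndex, reads, genome: Genome,
                snp_hash: SnpHash | None = None,
                params: AlignParams | None = None) -> dict:
    """Align a collection of reads; returns {read id: [SplicedAlignment, ...]}."""
    return {r.id: align_read(index, r, genome, snp_hash, params) for r in reads}
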