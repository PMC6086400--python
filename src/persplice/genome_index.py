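"""Suffix-array index over reference contigs plus SNP-mers.

The index answers *semi-maximal prefix* queries: for a query suffix it returns
every indexed position whose exact match with the query is at least a minimum
length (30 bp by default), each position reported at its maximal match length.
This recovers all plausible seed placements rather than only the single
longest one, which is what lets a read whose prefix is interrupted by a SNP
or a sequencing error still seed at the correct locus.

Construction uses a numpy prefix-doubling sort plus a Kasai LCP pass; the
suffix order is lexicographic with sentinel < A < C < G < T < N, and a
sentinel byte separates catalog sequences so no match ever crosses one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import SENTINEL, encode, encode_query
from .io_formats import SequenceRecord, SnpVariant
from .snpmer import SnpMer, snpmer_to_reference

__all__ = [
    "SeqIndex",
    "PrefixHit",
    "build_index",
    "semi_maximal_prefix_search",
    "iterative_segment_search",
]

INDEX_FORMAT_VERSION = 1
_KMER = 16  # k-mer length of the lossless presence screen (see has_seed_kmer)


@dataclass(frozen=True)
class PrefixHit:
    """A read-substring-to-genome exact match.

    query_offset/length locate the match in the query; seq_id/seq_offset in
    the indexed catalog sequence. For SNP-mer hits, ref_start0 and snps hold
    the converted reference coordinate and the embedded SNPs covered.
    """

    query_offset: int
    length: int
    seq_id: int
    seq_offset: int
    origin: str  # 'reference' | 'snpmer'
    chrom: str
    ref_start0: int
    snps: tuple = ()

    @property
    def diag(self) -> int:
        return self.ref_start0 - self.query_offset


def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array; correct for any integer alphabet."""
    n = t.size
    rank = t.astype(np.intp)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.intp)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.intp)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.intp)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def _lcp_array(text: bytes, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[r] = lcp(SA[r-1], SA[r])."""
    n = len(text)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    rank_l = rank.tolist()
    sa_l = sa.tolist()
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return np.asarray(lcp, dtype=np.int64)


class SeqIndex:
    """Suffix array + LCP over a catalog of sequences (contigs then SNP-mers)."""

    def __init__(self, contigs, snpmers=(), min_match: int = 30,
                 max_hits_per_length: int = 64):
        if not contigs:
            raise ValueError("index needs at least one contig")
        if min_match < 1:
            raise ValueError("min_match must be >= 1")
        self.contigs = list(contigs)
        self.snpmers = list(snpmers)
        self.min_match = min_match
        self.max_hits_per_length = max_hits_per_length

        pieces = []
        starts = []
        lengths = []
        pos = 0
        for rec in self.contigs:
            starts.append(pos)
            lengths.append(len(rec.seq))
            pieces.append(encode(rec.seq))
            pieces.append(np.array([SENTINEL], dtype=np.uint8))
            pos += len(rec.seq) + 1
        for mer in self.snpmers:
            starts.append(pos)
            lengths.append(len(mer.seq))
            pieces.append(encode(mer.seq))
            pieces.append(np.array([SENTINEL], dtype=np.uint8))
            pos += len(mer.seq) + 1
        self.text = np.concatenate(pieces)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.n_contigs = len(self.contigs)
        self.sa = _suffix_array(self.text)
        self.lcp = _lcp_array(self.text.tobytes(), self.sa)
        self._text_bytes = self.text.tobytes()
        self._kmer_set = self._build_kmer_set()

    # -- k-mer presence screen -------------------------------------------
    def _build_kmer_set(self) -> set[int]:
        ks: set[int] = set()
        k = _KMER
        for start, length in zip(self.starts.tolist(), self.lengths.tolist()):
            if length < k:
                continue
            seg = self.text[start:start + length].astype(np.int64)
            h = np.zeros(length - k + 1, dtype=np.int64)
            for j in range(k):
                h = h * 7 + seg[j:length - k + 1 + j]
            ks.update(h.tolist())
        return ks

    def has_seed_kmer(self, query_enc: np.ndarray) -> bool:
        """Lossless pre-screen: any exact match of length >= 30 in the index
        must contain one of the query's 16-mers sampled at stride 8."""
        k = _KMER
        n = query_enc.size
        if n < k:
            return True
        q = query_enc.astype(np.int64)
        for off in range(0, n - k + 1, 8):
            h = 0
            for j in range(k):
                h = h * 7 + int(q[off + j])
            if h in self._kmer_set:
                return True
        # cover the final window as well
        h = 0
        for j in range(k):
            h = h * 7 + int(q[n - k + j])
        return h in self._kmer_set

    # -- core search ------------------------------------------------------
    def _common_prefix(self, pos: int, q: np.ndarray) -> int:
        t = self.text
        m = min(q.size, t.size - pos)
        if m == 0:
            return 0
        neq = t[pos:pos + m] != q[:m]
        idx = int(np.argmax(neq))
        return idx if neq[idx] else m

    def _suffix_less_than(self, pos: int, q: np.ndarray) -> bool:
        k = self._common_prefix(pos, q)
        if k == q.size:
            return False  # query is a prefix of the suffix -> suffix >= query
        if pos + k >= self.text.size:
            return True  # suffix ran out (sentinel-terminated) -> smaller
        return self.text[pos + k] < q[k]

    def search(self, query_enc: np.ndarray, query_offset: int,
               min_len: int | None = None, cap: int | None = None):
        """Return [(concat_pos, match_len), ...] for the query suffix.

        Every indexed position whose maximal exact match with
        query[query_offset:] is at least min_len is returned once, at that
        maximal length, capped (deterministically, in suffix-array order) at
        `cap` hits per length.
        """
        if min_len is None:
            min_len = self.min_match
        if cap is None:
            cap = self.max_hits_per_length
        q = query_enc[query_offset:]
        if q.size < min_len:
            return []
        sa, lcp = self.sa, self.lcp
        n = sa.size
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            if self._suffix_less_than(int(sa[mid]), q):
                lo = mid + 1
            else:
                hi = mid
        p = lo
        hits: list[tuple[int, int]] = []
        per_len: dict[int, int] = {}

        def record(pos: int, length: int) -> None:
            c = per_len.get(length, 0)
            if c < cap:
                per_len[length] = c + 1
                hits.append((pos, length))

        lcp_l = lcp
        if p < n:
            cur = self._common_prefix(int(sa[p]), q)
            i = p
            while i < n and cur >= min_len:
                record(int(sa[i]), cur)
                i += 1
                if i < n:
                    cur = min(cur, int(lcp_l[i]))
        if p > 0:
            cur = self._common_prefix(int(sa[p - 1]), q)
            i = p - 1
            while i >= 0 and cur >= min_len:
                record(int(sa[i]), cur)
                if i > 0:
                    cur = min(cur, int(lcp_l[i]))
                i -= 1
        return hits

    def locate(self, concat_pos: int) -> tuple[int, int]:
        """Map a concatenation position to (catalog sequence id, offset)."""
        idx = int(np.searchsorted(self.starts, concat_pos, side="right")) - 1
        return idx, concat_pos - int(self.starts[idx])

    def make_hit(self, concat_pos: int, length: int, query_offset: int) -> PrefixHit:
        seq_id, off = self.locate(concat_pos)
        if seq_id < self.n_contigs:
            rec = self.contigs[seq_id]
            return PrefixHit(query_offset, length, seq_id, off, "reference",
                             rec.name, off)
        mer = self.snpmers[seq_id - self.n_contigs]
        chrom, ref_start, covered = snpmer_to_reference(mer, off, length)
        return PrefixHit(query_offset, length, seq_id, off, "snpmer",
                         chrom, ref_start, covered)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "index.npz", text=self.text, sa=self.sa, lcp=self.lcp,
                 starts=self.starts, lengths=self.lengths)
        meta = {
            "format_version": INDEX_FORMAT_VERSION,
            "min_match": self.min_match,
            "max_hits_per_length": self.max_hits_per_length,
            "contigs": [c.name for c in self.contigs],
            "snpmers": [
                {
                    "seq": m.seq,
                    "chrom": m.chrom,
                    "ref_start0": m.ref_start0,
                    "central": [m.central.chrom, m.central.pos0, m.central.ref,
                                m.central.alt, m.central.phase],
                    "embedded": [[off, [s.chrom, s.pos0, s.ref, s.alt, s.phase]]
                                 for off, s in m.embedded],
                    "haplotype": m.haplotype,
                }
                for m in self.snpmers
            ],
        }
        (d / "catalog.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "SeqIndex":
        d = Path(directory)
        meta = json.loads((d / "catalog.json").read_text())
        if meta["format_version"] != INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format {meta['format_version']}")
        arrays = np.load(d / "index.npz")
        obj = cls.__new__(cls)
        obj.text = arrays["text"]
        obj.sa = arrays["sa"]
        obj.lcp = arrays["lcp"]
        obj.starts = arrays["starts"]
        obj.lengths = arrays["lengths"]
        obj.min_match = meta["min_match"]
        obj.max_hits_per_length = meta["max_hits_per_length"]
        obj.n_contigs = len(meta["contigs"])
        decode = {1: "A", 2: "C", 3: "G", 4: "T", 5: "N"}
        contigs = []
        for i, name in enumerate(meta["contigs"]):
            start, length = int(obj.starts[i]), int(obj.lengths[i])
            seq = "".join(decode[b] for b in obj.text[start:start + length].tolist())
            contigs.append(SequenceRecord(name, seq))
        obj.contigs = contigs
        obj.snpmers = [
            SnpMer(
                m["seq"], m["chrom"], m["ref_start0"],
                SnpVariant(*m["central"]),
                tuple((off, SnpVariant(*s)) for off, s in m["embedded"]),
                m["haplotype"],
            )
            for m in meta["snpmers"]
        ]
        obj._text_bytes = obj.text.tobytes()
        obj._kmer_set = obj._build_kmer_set()
        return obj


def build_index(contigs, snpmers=(), min_match: int = 30, **kw) -> SeqIndex:
    """Build a deterministic index over reference contigs plus SNP-mers."""
    return SeqIndex(contigs, snpmers, min_match=min_match, **kw)


def semi_maximal_prefix_search(index: SeqIndex, query: str, query_offset: int = 0,
                               min_len: int | None = None,
                               cap: int | None = None) -> list[PrefixHit]:
    """All maximal occurrences of query[query_offset:] with length >= min_len."""
    q = encode_query(query)
    raw = index.search(q, query_offset, min_len=min_len, cap=cap)
    return [index.make_hit(pos, length, query_offset) for pos, length in raw]


def iterative_segment_search(index: SeqIndex, read_seq: str,
                             min_len: int | None = None,
                             seed_min: int = 18) -> list[PrefixHit]:
    """Tile a read with semi-maximal prefix matches.

    Searches from the current offset, advances past the longest match found
    (or by 1 bp when nothing reaches min_len) until fewer than min_len bases
    remain. SNP-mer hits come back already converted to reference coordinates
    and tagged with the SNPs they cover. Hits shorter than seed_min are
    discarded as unreliable seeds.
    """
    if min_len is None:
        min_len = index.min_match
    q = encode_query(read_seq)
    n = q.size
    hits: list[PrefixHit] = []
    off = 0
    while off + min_len <= n:
        raw = index.search(q, off, min_len=min_len)
        if not raw:
            off += 1
            continue
        best = max(length for _, length in raw)
        for pos, length in raw:
            if length >= seed_min:
                hits.append(index.make_hit(pos, length, off))
        off += best
    return hits
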