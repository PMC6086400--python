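"""Nucleotide encoding helpers shared across the package.

Bases are encoded into small integers with sentinel < A < C < G < T < N so
that suffix-array order over concatenated sequences is well defined and a
separator byte (0) never matches any base. Query sequences encode N as a
distinct value so that an N in a read never matches an N in the genome.
"""

from __future__ import annotations

import numpy as np

SENTINEL = 0
_CODES = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}

_ENC_TABLE = np.full(256, np.uint8(5))  # unknown characters behave like N
for _b, _v in _CODES.items():
    _ENC_TABLE[ord(_b)] = _v

_RC = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=1..T=4, N=5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC_TABLE[raw]


def encode_query(seq: str) -> np.ndarray:
    """Encode a query so that N (code 6) never matches a target base."""
    enc = encode(seq).copy()
    enc[enc == 5] = 6
    return enc


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class Genome:
    """In-memory reference: per-contig sequence strings plus encoded arrays."""

    def __init__(self, records):
        self.seq: dict[str, str] = {r.name: r.seq for r in records}
        self.enc: dict[str, np.ndarray] = {n: encode(s) for n, s in self.seq.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.seq

    def length(self, name: str) -> int:
        return len(self.seq[name])

    def contigs(self):
        return list(self.seq)

    def fetch(self, name: str, start: int, end: int) -> str:
        return self.seq[name][max(0, start):end]
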