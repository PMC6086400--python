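"""Splice-site dinucleotide motifs.

A junction's motif is the pair (first two intronic bases, last two intronic
bases) read on the forward genome strand. Canonical pairs on the plus strand
are GT-AG, GC-AG and AT-AC; their reverse-strand counterparts appear on the
forward strand as CT-AC, CT-GC and GT-AT. GT-AG (and its reverse CT-AC) is
the primary class used for tie-breaking.
"""

from __future__ import annotations

PLUS_PAIRS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})
MINUS_PAIRS = frozenset({("CT", "AC"), ("CT", "GC"), ("GT", "AT")})
CANONICAL_PAIRS = PLUS_PAIRS | MINUS_PAIRS
PRIMARY_PAIRS = frozenset({("GT", "AG"), ("CT", "AC")})

# Motif sets for candidate splice-site scanning, keyed by (side, strand).
# For plus-strand junctions the donor dinucleotide sits at the intron start;
# for minus-strand junctions the biological donor appears (reverse
# complemented) at the intron end on the forward strand.
SIDE_MOTIFS = {
    ("donor", "+"): frozenset({"GT", "GC", "AT"}),
    ("acceptor", "+"): frozenset({"AG", "AC"}),
    ("donor", "-"): frozenset({"AC", "GC", "AT"}),
    ("acceptor", "-"): frozenset({"CT", "GT"}),
}


def is_canonical(donor: str, acceptor: str) -> bool:
    return (donor, acceptor) in CANONICAL_PAIRS


def pair_strand(donor: str, acceptor: str) -> str:
    """Strand implied by a motif; motif-ambiguous pairs default to '+'."""
    if (donor, acceptor) in PLUS_PAIRS:
        return "+"
    if (donor, acceptor) in MINUS_PAIRS:
        return "-"
    return "+"


def classify_motifs(ref_motif: str, pers_motif: str) -> str:
    """'gain' when SNPs turn a noncanonical motif canonical, 'loss' for the
    reverse, 'none' otherwise. Motifs are 4-character strings (donor+acceptor)."""
    ref_can = is_canonical(ref_motif[:2], ref_motif[2:])
    pers_can = is_canonical(pers_motif[:2], pers_motif[2:])
    if not ref_can and pers_can:
        return "gain"
    if ref_can and not pers_can:
        return "loss"
    return "none"
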