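"""Readers and writers for the standard formats the aligner touches.

Coordinate convention: everything in memory is 0-based, half-open. The shift
to 1-based coordinates happens only here, at SAM / table serialization time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pysam

from ._seq import revcomp

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SequenceRecord",
    "ReadRecord",
    "SnpVariant",
    "JunctionRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_vcf_snps",
    "validate_snps",
    "write_sam",
    "write_junction_table",
    "write_allelic_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named contig: uppercase nucleotide string over {A,C,G,T,N}."""

    name: str
    seq: str


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; mate is 1/2 for paired data, 0 for unpaired."""

    id: str
    seq: str
    qual: str
    mate: int = 0

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id}: sequence length {len(self.seq)} != quality length {len(self.qual)}"
            )


@dataclass(frozen=True, order=True)
class SnpVariant:
    """A biallelic single-nucleotide substitution, the unit of personalization.

    phase: which haplotype carries the alternate allele -- 'hap1', 'hap2',
    'both' (homozygous alternate) or 'unphased'.
    """

    chrom: str
    pos0: int
    ref: str
    alt: str
    phase: str = "unphased"


@dataclass
class JunctionRecord:
    """An intron call: donor_pos0 is the first intronic base, acceptor_pos0 the last.

    ref_motif / pers_motif are the 4-character donor+acceptor dinucleotides
    under the reference and the personal (SNP-substituted) alleles, e.g. 'GTAG'.
    polymorphic is 'gain' when a SNP converts a noncanonical motif to canonical,
    'loss' for the reverse, 'none' otherwise.
    """

    chrom: str
    donor_pos0: int
    acceptor_pos0: int
    strand: str
    ref_motif: str
    pers_motif: str
    support: int = 0
    polymorphic: str = "none"

    @property
    def intron_length(self) -> int:
        return self.acceptor_pos0 - self.donor_pos0 + 1

    def key(self):
        return (self.chrom, self.donor_pos0, self.acceptor_pos0, self.strand)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file; multi-line sequences are concatenated and uppercased."""
    records: list[SequenceRecord] = []
    name = None
    chunks: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks).upper()))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks).upper()))
    if n_lines == 0 or not records:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path, mate: int = 0) -> list[ReadRecord]:
    reads = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            if entry.quality is None:
                raise FormatError(f"{path}: record {entry.name} has no quality string")
            reads.append(ReadRecord(entry.name, entry.sequence.upper(), entry.quality, mate))
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# VCF

_BASES = frozenset("ACGT")


def read_vcf_snps(path, sample_index: int = 0, phased_required: bool = False) -> list[SnpVariant]:
    """Load biallelic SNVs for one sample from a VCF 4.x file.

    File positions are 1-based; returned pos0 is 0-based. Indels and
    homozygous-reference records are skipped with a logged count. Multi-allelic
    sites keep the first ALT only (remaining ALTs are logged and dropped).
    Phase is taken from the GT separator: '0|1' puts the alternate on hap2,
    '1|0' on hap1, '1|1' on both; '/'-separated genotypes are unphased.
    """
    snps: list[SnpVariant] = []
    skipped = {"indel": 0, "extra_alt": 0, "hom_ref": 0, "missing_gt": 0}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        if sample_index >= len(samples):
            raise FormatError(f"{path}: sample index {sample_index} out of range")
        sample = samples[sample_index]
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            if not alts:
                continue
            if len(alts) > 1:
                skipped["extra_alt"] += len(alts) - 1
            alt = alts[0]
            ref = rec.ref
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skipped["indel"] += 1
                continue
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                if phased_required:
                    raise FormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} has no GT for sample "
                        f"{sample}, required in phased mode"
                    )
                skipped["missing_gt"] += 1
                continue
            if not any(a == 1 for a in gt):
                skipped["hom_ref"] += 1
                continue
            if len(gt) == 1:
                phase = "both"
            elif call.phased:
                if gt == (1, 1):
                    phase = "both"
                elif gt == (0, 1):
                    phase = "hap2"
                else:  # (1, 0)
                    phase = "hap1"
            else:
                phase = "both" if gt == (1, 1) else "unphased"
            if phased_required and phase == "unphased":
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} is unphased; phased "
                    "genotypes are required in phased mode (use unphased mode instead)"
                )
            snps.append(SnpVariant(rec.chrom, rec.pos - 1, ref, alt, phase))
    dropped = {k: v for k, v in skipped.items() if v}
    if dropped:
        log.info("read_vcf_snps(%s): kept %d SNVs, skipped %s", path, len(snps), dropped)
    return snps


def validate_snps(genome, snps) -> None:
    """Check every SNP's REF base against the loaded genome; mismatch is an error."""
    for s in snps:
        if s.chrom not in genome:
            raise FormatError(f"SNP {s.chrom}:{s.pos0 + 1}: unknown contig")
        if not (0 <= s.pos0 < genome.length(s.chrom)):
            raise FormatError(f"SNP {s.chrom}:{s.pos0 + 1}: position outside contig")
        base = genome.seq[s.chrom][s.pos0]
        if base != s.ref:
            raise FormatError(
                f"SNP {s.chrom}:{s.pos0 + 1}: REF {s.ref} does not match genome base {base}"
            )
        if s.ref == s.alt or s.alt not in _BASES:
            raise FormatError(f"SNP {s.chrom}:{s.pos0 + 1}: invalid alleles {s.ref}>{s.alt}")


# ---------------------------------------------------------------------------
# SAM

_CIGAR_M, _CIGAR_N, _CIGAR_S = 0, 3, 4


def write_sam(results, reads, contigs, path, cmdline: str | None = None) -> None:
    """Write alignments as plain SAM.

    results: mapping read id -> list of SplicedAlignment (empty list = unmapped).
    reads:   mapping read id -> ReadRecord (provides SEQ/QUAL).
    contigs: list of SequenceRecord providing the @SQ header lines.

    The first alignment of a read is primary; the rest carry the secondary
    flag. NM holds the raw mismatch count; the SNP-excluded count goes in the
    ZS tag, the seed origin in ZO, per-junction polymorphic flags in ZP, and
    the number of reported alignments in NH.
    """
    from . import __version__

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": len(c.seq)} for c in contigs],
        "PG": [{"ID": "persplice", "PN": "persplice", "VN": __version__,
                "CL": cmdline or "persplice"}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c.name: i for i, c in enumerate(contigs)}
        for read_id in results:
            read = reads[read_id]
            alns = results[read_id]
            if not alns:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = read.id
                seg.flag = 4
                seg.query_sequence = read.seq
                seg.query_qualities = pysam.qualitystring_to_array(read.qual)
                out.write(seg)
                continue
            for rank, aln in enumerate(alns):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = read.id
                flag = 0
                if aln.orientation == "revcomp":
                    flag |= 16
                if rank > 0:
                    flag |= 256
                seg.flag = flag
                seg.reference_id = tid[aln.chrom]
                seg.reference_start = aln.blocks[0].ref_start
                seg.mapping_quality = 60 if len(alns) == 1 else 0
                cig = []
                if aln.soft_clip5:
                    cig.append((_CIGAR_S, aln.soft_clip5))
                for i, blk in enumerate(aln.blocks):
                    if i > 0:
                        prev = aln.blocks[i - 1]
                        cig.append((_CIGAR_N, blk.ref_start - (prev.ref_start + prev.length)))
                    cig.append((_CIGAR_M, blk.length))
                if aln.soft_clip3:
                    cig.append((_CIGAR_S, aln.soft_clip3))
                seg.cigartuples = cig
                oriented = read.seq if aln.orientation == "forward" else revcomp(read.seq)
                qual = read.qual if aln.orientation == "forward" else read.qual[::-1]
                seg.query_sequence = oriented
                seg.query_qualities = pysam.qualitystring_to_array(qual)
                seg.set_tag("NM", int(aln.mism_raw))
                seg.set_tag("ZS", int(aln.mism_snp_excluded))
                seg.set_tag("ZO", aln.origin)
                seg.set_tag("NH", len(alns))
                if aln.junctions:
                    seg.set_tag("ZP", ",".join(j.polymorphic for j in aln.junctions))
                out.write(seg)


# ---------------------------------------------------------------------------
# Tab-delimited tables


def write_junction_table(junctions, path) -> None:
    """Tab-delimited junction catalog with 1-based inclusive intron coordinates."""
    import pandas as pd

    rows = [
        {
            "chrom": j.chrom,
            "intron_start1": j.donor_pos0 + 1,
            "intron_end1": j.acceptor_pos0 + 1,
            "strand": j.strand,
            "ref_motif": f"{j.ref_motif[:2]}-{j.ref_motif[2:]}",
            "pers_motif": f"{j.pers_motif[:2]}-{j.pers_motif[2:]}",
            "support": j.support,
            "polymorphic": j.polymorphic,
        }
        for j in sorted(junctions, key=lambda j: j.key())
    ]
    cols = ["chrom", "intron_start1", "intron_end1", "strand",
            "ref_motif", "pers_motif", "support", "polymorphic"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_allelic_table(counts, path) -> None:
    import pandas as pd

    rows = [
        {
            "chrom": c.snp.chrom,
            "pos1": c.snp.pos0 + 1,
            "ref": c.snp.ref,
            "alt": c.snp.alt,
            "ref_count": c.ref_count,
            "alt_count": c.alt_count,
            "other_count": c.other_count,
            "ratio": round(c.ratio, 6) if c.ratio is not None else "NA",
        }
        for c in sorted(counts, key=lambda c: (c.snp.chrom, c.snp.pos0))
    ]
    cols = ["chrom", "pos1", "ref", "alt", "ref_count", "alt_count", "other_count", "ratio"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
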