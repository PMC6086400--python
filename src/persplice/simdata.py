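"""Synthetic diploid RNA-seq data with full ground truth.

Generates, with no external downloads: a random reference genome carrying
multi-exon genes with canonical GT-AG introns; heterozygous SNPs, including
splice-site plants that create (reference GG-AG restored to GT-AG by the
alternate allele) or destroy (AG corrupted to AC) canonical junctions; and
paired-end reads drawn uniformly from the two haplotypes under configurable
substitution / indel / base-error frequencies. Every read records its origin
haplotype, reference blocks and planted errors, so alignment accuracy,
allelic balance and junction recovery can all be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp
from .io_formats import ReadRecord, SequenceRecord, SnpVariant

__all__ = [
    "SimProfile",
    "TranscriptModel",
    "ReadTruth",
    "GroundTruth",
    "PlantResult",
    "simulate_genome",
    "plant_snps",
    "build_haplotypes",
    "simulate_reads",
    "simulate_individual",
    "auto_snps",
    "empirical_base_error",
    "write_vcf",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimProfile:
    """Variant / error frequencies and read geometry.

    The low-error defaults are substitution 0.001, indel 0.0005 and per-base
    sequencing error 0.005; the high-error preset is fivefold each.
    """

    subst_freq: float = 0.001
    indel_freq: float = 0.0005
    base_err_freq: float = 0.005
    read_len: int = 75
    insert_len: int = 200
    n_pairs: int = 1000
    seed: int = 0

    @classmethod
    def low_error(cls, **kw) -> "SimProfile":
        return cls(**kw)

    @classmethod
    def high_error(cls, **kw) -> "SimProfile":
        return cls(subst_freq=0.005, indel_freq=0.0025, base_err_freq=0.025, **kw)

    @classmethod
    def error_free(cls, **kw) -> "SimProfile":
        return cls(subst_freq=0.0, indel_freq=0.0, base_err_freq=0.0, **kw)


@dataclass(frozen=True)
class TranscriptModel:
    name: str
    chrom: str
    strand: str
    exons: tuple  # of (start0, end0) half-open, increasing

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """(donor_pos0, acceptor_pos0) per intron: first and last intronic base."""
        return [(self.exons[i][1], self.exons[i + 1][0] - 1)
                for i in range(len(self.exons) - 1)]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class ReadTruth:
    """Per-read origin record; fwd_* fields are in forward-genome orientation."""

    read_id: str
    transcript: str
    haplotype: int
    orientation: str  # '+' mate sequenced forward, '-' reverse-complemented
    blocks: tuple  # of (ref_start0, length), forward orientation
    fwd_clean_seq: str  # forward-orientation sequence before errors
    error_offsets: tuple  # forward-orientation offsets of planted base errors
    has_indel: bool


@dataclass
class GroundTruth:
    reads: dict  # read_id -> ReadTruth
    junction_support: dict  # (chrom, donor0, acceptor0) -> mates spanning with >=8bp anchors


def simulate_genome(length: int = 100_000, n_genes: int = 20,
                    exons_per_gene: int = 4, seed: int = 0,
                    exon_len=(90, 220), intron_len=(61, 300),
                    chrom: str = "chr1"):
    """Random genome with evenly spaced multi-exon genes and GT-AG introns.

    Deterministic per seed. Exon minimum (90 bp) keeps single-junction reads
    for typical short-read lengths; intron boundaries are overwritten with
    canonical dinucleotides. Raises when the genes do not fit.
    """
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    territory = length // n_genes
    models = []
    for g in range(n_genes):
        p = g * territory + 50
        exons = []
        for e in range(exons_per_gene):
            elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((p, p + elen))
            p += elen
            if e < exons_per_gene - 1:
                ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
                arr[p] = "G"
                arr[p + 1] = "T"
                arr[p + ilen - 2] = "A"
                arr[p + ilen - 1] = "G"
                p += ilen
        if p > (g + 1) * territory or p > length:
            raise ValueError(
                f"genome of length {length} cannot pack {n_genes} genes of "
                f"{exons_per_gene} exons; increase length"
            )
        models.append(TranscriptModel(f"gene{g:03d}", chrom, "+", tuple(exons)))
    return SequenceRecord(chrom, "".join(arr.tolist())), models


def _retain_intron(model: TranscriptModel, j: int) -> TranscriptModel:
    """Transcript variant with intron j retained (exons j, j+1 merged)."""
    exons = list(model.exons)
    merged = (exons[j][0], exons[j + 1][1])
    new = tuple(exons[:j] + [merged] + exons[j + 2:])
    return TranscriptModel(f"{model.name}.ri{j}", model.chrom, model.strand, new)


@dataclass
class PlantResult:
    """Planted cohort: possibly edited reference, per-individual SNPs and the
    per-haplotype transcript forms each individual expresses."""

    genome: SequenceRecord
    models: list
    snps_by_individual: dict  # ind -> list[SnpVariant]
    transcripts_by_individual: dict  # ind -> {1: [models], 2: [models]}
    planted: list  # dicts: kind, chrom, donor0, acceptor0, snp, carriers, gene


def plant_snps(genome: SequenceRecord, models, n_exonic: int = 200,
               n_gain: int = 0, n_loss: int = 0, seed: int = 0,
               n_individuals: int = 1, carrier_prob: float = 0.5) -> PlantResult:
    """Plant heterozygous exonic SNPs and splice-site polymorphisms.

    Gain plants edit the REFERENCE donor GT to GG and register the SNP G>T
    restoring it, so the canonical junction exists only under the alternate
    allele; loss plants leave the reference canonical and register an
    acceptor SNP G>C (AG>AC). Carriers express the spliced form on the
    haplotype carrying the restoring allele (gain) and retain the intron on
    the haplotype carrying the corrupting allele (loss); the affected intron
    is retained wherever the canonical site is absent.

    Exonic SNPs are shared by all individuals (same phases); splice-site
    plants draw carriers per individual with probability carrier_prob,
    resampled so that cohorts with >= 2 individuals have at least one carrier
    and one non-carrier.
    """
    rng = np.random.default_rng(seed)
    arr = np.array(list(genome.seq))
    chrom = genome.name
    individuals = [f"ind{k:02d}" for k in range(n_individuals)]
    if n_gain + n_loss > len(models):
        raise ValueError("more splice-site plants than genes")

    # choose the genes and middle junctions used for splice plants
    plant_genes = rng.choice(len(models), size=n_gain + n_loss, replace=False)
    planted = []
    # ind -> gene index -> (junction index, hap expressing the spliced form or
    #                       retaining the intron, kind)
    splice_state = {ind: {} for ind in individuals}
    splice_snps = {ind: [] for ind in individuals}

    def pick_carriers():
        while True:
            mask = rng.random(n_individuals) < carrier_prob
            if n_individuals == 1:
                return [individuals[0]]
            if mask.any() and not mask.all():
                return [ind for ind, m in zip(individuals, mask) if m]

    for k, gidx in enumerate(plant_genes):
        kind = "gain" if k < n_gain else "loss"
        model = models[int(gidx)]
        jidx = len(model.junctions) // 2
        donor0, acceptor0 = model.junctions[jidx]
        carriers = pick_carriers()
        if kind == "gain":
            arr[donor0 + 1] = "G"  # reference motif becomes GG-AG
            snp_pos, ref, alt = donor0 + 1, "G", "T"
        else:
            snp_pos, ref, alt = acceptor0, "G", "C"  # personal motif GT-AC
        for ind in individuals:
            if ind in carriers:
                hap = int(rng.integers(1, 3))
                phase = f"hap{hap}"
                splice_snps[ind].append(SnpVariant(chrom, snp_pos, ref, alt, phase))
                splice_state[ind][int(gidx)] = (jidx, hap, kind)
            else:
                splice_state[ind][int(gidx)] = (jidx, None, kind)
        planted.append({
            "kind": kind, "chrom": chrom, "donor0": donor0,
            "acceptor0": acceptor0,
            "snp": SnpVariant(chrom, snp_pos, ref, alt, "unphased"),
            "carriers": tuple(carriers), "gene": model.name,
        })

    # exonic heterozygous SNPs, shared across individuals
    exon_positions = np.concatenate([
        np.arange(s, e) for m in models for s, e in m.exons
    ]) if models else np.array([], dtype=int)
    reserved = {p["snp"].pos0 for p in planted}
    pool = np.array([p for p in exon_positions.tolist() if p not in reserved])
    if n_exonic > pool.size:
        raise ValueError("not enough exonic positions for requested SNPs")
    chosen = rng.choice(pool, size=n_exonic, replace=False)
    exonic = []
    for pos in sorted(int(p) for p in chosen):
        ref = str(arr[pos])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        phase = "hap1" if rng.random() < 0.5 else "hap2"
        exonic.append(SnpVariant(chrom, pos, ref, alt, phase))

    new_genome = SequenceRecord(chrom, "".join(arr.tolist()))
    snps_by_ind = {ind: sorted(exonic + splice_snps[ind]) for ind in individuals}

    transcripts_by_ind = {}
    for ind in individuals:
        per_hap = {1: [], 2: []}
        for gidx, model in enumerate(models):
            state = splice_state[ind].get(gidx)
            for hap in (1, 2):
                if state is None:
                    per_hap[hap].append(model)
                    continue
                jidx, carrier_hap, kind = state
                if kind == "gain":
                    # spliced form only on the haplotype with the restored GT
                    spliced = carrier_hap == hap
                else:
                    # loss: the haplotype with the corrupted AG retains
                    spliced = carrier_hap != hap
                per_hap[hap].append(model if spliced else _retain_intron(model, jidx))
        transcripts_by_ind[ind] = per_hap
    return PlantResult(new_genome, list(models), snps_by_ind,
                       transcripts_by_ind, planted)


def build_haplotypes(genome: SequenceRecord, snps) -> tuple[str, str]:
    """Apply phased SNPs to the reference; returns (hap1, hap2) sequences."""
    h1 = np.array(list(genome.seq))
    h2 = h1.copy()
    for s in snps:
        if s.phase == "unphased":
            raise ValueError(f"SNP {s.chrom}:{s.pos0 + 1} must be phased to build haplotypes")
        if s.phase in ("hap1", "both"):
            h1[s.pos0] = s.alt
        if s.phase in ("hap2", "both"):
            h2[s.pos0] = s.alt
    return "".join(h1.tolist()), "".join(h2.tolist())


def auto_snps(genome: SequenceRecord, subst_freq: float, seed: int = 0):
    """Auto-generate haplotype substitutions: each reference base mutates on
    each haplotype independently with probability subst_freq."""
    rng = np.random.default_rng(seed)
    n = len(genome.seq)
    snps = []
    used = set()
    for hap in ("hap1", "hap2"):
        positions = np.nonzero(rng.random(n) < subst_freq)[0]
        for pos in positions.tolist():
            if pos in used:
                continue
            used.add(pos)
            ref = genome.seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snps.append(SnpVariant(genome.name, pos, ref, alt, hap))
    return sorted(snps)


def _blocks_from_map(ref_map: np.ndarray):
    """Split a per-base reference-coordinate map into contiguous blocks."""
    breaks = np.nonzero(np.diff(ref_map) != 1)[0]
    blocks = []
    start = 0
    for b in breaks.tolist():
        blocks.append((int(ref_map[start]), b - start + 1))
        start = b + 1
    blocks.append((int(ref_map[start]), len(ref_map) - start))
    return tuple(blocks)


def _apply_errors(clean: str, rng, profile: SimProfile):
    """Per-base substitution errors plus (rarely) a single 1 bp indel."""
    chars = list(clean)
    L = len(chars)
    err_pos = np.nonzero(rng.random(L) < profile.base_err_freq)[0]
    for p in err_pos.tolist():
        chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
    has_indel = False
    if profile.indel_freq > 0:
        ind_pos = np.nonzero(rng.random(L) < profile.indel_freq)[0]
        if ind_pos.size:
            has_indel = True
            p = int(ind_pos[0])
            if rng.random() < 0.5:  # deletion: shift left, pad with random base
                del chars[p]
                chars.append(str(rng.choice(list("ACGT"))))
            else:  # insertion: random base, truncate to read length
                chars.insert(p, str(rng.choice(list("ACGT"))))
                chars = chars[:L]
    return "".join(chars), tuple(int(p) for p in err_pos.tolist()), has_indel


def simulate_reads(models_by_hap, haplotypes: tuple[str, str],
                   profile: SimProfile, chrom: str = "chr1"):
    """Draw paired-end reads uniformly over transcripts and haplotypes.

    models_by_hap: {1: [TranscriptModel...], 2: [...]} (a flat list is applied
    to both haplotypes). Mate 1 is sequenced forward from the fragment start,
    mate 2 reverse-complemented from the fragment end; fragment length equals
    profile.insert_len. Transcripts shorter than the insert are skipped.
    Deterministic per profile.seed. Returns (reads, GroundTruth).
    """
    if not isinstance(models_by_hap, dict):
        models_by_hap = {1: list(models_by_hap), 2: list(models_by_hap)}
    rng = np.random.default_rng(profile.seed)
    L, insert = profile.read_len, profile.insert_len
    prepared = {}
    for hap in (1, 2):
        entries = []
        hseq = haplotypes[hap - 1]
        for m in models_by_hap[hap]:
            if m.spliced_length < insert:
                continue
            tseq = "".join(hseq[s:e] for s, e in m.exons)
            tmap = np.concatenate([np.arange(s, e) for s, e in m.exons])
            entries.append((m, tseq, tmap))
        if not entries:
            raise ValueError(f"no transcript on haplotype {hap} is at least "
                             f"{insert} bp; cannot draw fragments")
        prepared[hap] = entries

    reads: list[ReadRecord] = []
    truths: dict[str, ReadTruth] = {}
    junction_support: dict[tuple, int] = {}
    qual = "I" * L
    for i in range(profile.n_pairs):
        hap = int(rng.integers(1, 3))
        model, tseq, tmap = prepared[hap][int(rng.integers(len(prepared[hap])))]
        start = int(rng.integers(0, len(tseq) - insert + 1))
        frag = tseq[start:start + insert]
        frag_map = tmap[start:start + insert]
        for mate, (fwd_clean, fwd_map, orient) in enumerate((
            (frag[:L], frag_map[:L], "+"),
            (frag[insert - L:], frag_map[insert - L:], "-"),
        ), start=1):
            fwd_err, err_offs, has_indel = _apply_errors(fwd_clean, rng, profile)
            seq = fwd_err if orient == "+" else revcomp(fwd_err)
            read_id = f"r{i:06d}/{mate}"
            reads.append(ReadRecord(read_id, seq, qual, mate))
            blocks = _blocks_from_map(fwd_map)
            truths[read_id] = ReadTruth(read_id, model.name, hap, orient,
                                        blocks, fwd_clean, err_offs, has_indel)
            offset = 0
            for bi in range(len(blocks) - 1):
                donor0 = blocks[bi][0] + blocks[bi][1]
                acceptor0 = blocks[bi + 1][0] - 1
                if blocks[bi][1] >= 8 and blocks[bi + 1][1] >= 8:
                    key = (chrom, donor0, acceptor0)
                    junction_support[key] = junction_support.get(key, 0) + 1
                offset += blocks[bi][1]
    return reads, GroundTruth(truths, junction_support)


def simulate_individual(plant: PlantResult, individual: str, profile: SimProfile):
    """Reads plus truth for one individual of a planted cohort."""
    haps = build_haplotypes(plant.genome, plant.snps_by_individual[individual])
    return simulate_reads(plant.transcripts_by_individual[individual], haps,
                          profile, chrom=plant.genome.name)


def empirical_base_error(reads, truth: GroundTruth):
    """(mismatching bases, total bases) over reads without indel errors,
    comparing each read with its clean origin sequence."""
    n_err = 0
    n_bases = 0
    for read in reads:
        t = truth.reads[read.id]
        if t.has_indel:
            continue
        fwd = read.seq if t.orientation == "+" else revcomp(read.seq)
        n_bases += len(fwd)
        n_err += sum(1 for a, b in zip(fwd, t.fwd_clean_seq) if a != b)
    return n_err, n_bases


def write_vcf(snps, contigs, path, sample: str = "SAMPLE") -> None:
    """Minimal VCF 4.2 writer for simulated genotypes (synthetic data only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c.name},length={len(c.seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for s in sorted(snps):
            gt = {"hap1": "1|0", "hap2": "0|1", "both": "1|1",
                  "unphased": "0/1"}[s.phase]
            fh.write(f"{s.chrom}\t{s.pos0 + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gt}\n")
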