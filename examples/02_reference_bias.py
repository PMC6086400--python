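"""Measure reference-allelic-ratio bias with and without SNP-mers.

Simulates balanced reads from both haplotypes of a diploid genome, aligns
them twice, and prints the mean reference allelic ratio over heterozygous
SNPs with at least ten allele-informative reads. Unbiased alignment centers
the ratio at 0.5; reference-only alignment inflates it.
"""

from persplice import (Genome, SnpHash, align_reads, build_index,
                       count_alleles, extract_phased_snpmers,
                       summarize_ratio_distribution)
from persplice.simdata import SimProfile, plant_snps, simulate_genome, simulate_individual

genome0, models = simulate_genome(50_000, 10, 4, seed=7)
plant = plant_snps(genome0, models, n_exonic=60, seed=8)
snps = plant.snps_by_individual["ind00"]
genome = Genome([plant.genome])
mers = extract_phased_snpmers([plant.genome], snps)

reads, _ = simulate_individual(plant, "ind00", SimProfile(n_pairs=6000, seed=9))
het = [s for s in snps if s.phase != "both"]
read_map = {r.id: r for r in reads}

for label, idx, sh in (
    ("SNP-aware", build_index([plant.genome], mers), SnpHash(snps)),
    ("reference-only", build_index([plant.genome]), SnpHash()),
):
    results = align_reads(idx, reads, genome, sh)
    counts = count_alleles(results, het, read_map)
    s = summarize_ratio_distribution(counts, min_reads=10)
    print(f"{label:15s} n_snps={s.n_snps_covered:3d} mean_ratio={s.mean:.4f} "
          f"skewness={s.skewness:+.3f}")

print("\nmean_ratio near 0.5 means both alleles align equally well; the "
      "reference-only mean sits above 0.5 because alternate-allele reads "
      "are preferentially lost.")
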