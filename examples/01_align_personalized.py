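"""Align reads carrying alternate alleles with and without SNP-mers.

Builds a small synthetic diploid, takes one read that carries a heterozygous
alternate allele near its end, and shows how the SNP-aware index aligns it
full-length while the plain reference index clips the allele away.
"""

from persplice import (Genome, ReadRecord, SnpHash, align_read, build_index,
                       extract_phased_snpmers)
from persplice.simdata import build_haplotypes, plant_snps, simulate_genome

genome0, models = simulate_genome(30_000, 6, 4, seed=1)
plant = plant_snps(genome0, models, n_exonic=30, seed=2)
snps = plant.snps_by_individual["ind00"]
genome = Genome([plant.genome])
haplotypes = build_haplotypes(plant.genome, snps)

# a haplotype read whose last base is the alternate allele of an exonic SNP
snp = next(s for s in snps
           if any(e[0] + 80 <= s.pos0 < e[1] for m in models for e in m.exons))
hap_seq = haplotypes[0 if snp.phase == "hap1" else 1]
seq = hap_seq[snp.pos0 - 74:snp.pos0 + 1]
read = ReadRecord("alt_read", seq, "I" * 75)

mers = extract_phased_snpmers([plant.genome], snps)
idx_aware = build_index([plant.genome], mers)
idx_ref = build_index([plant.genome])

for label, idx, sh in (("SNP-aware", idx_aware, SnpHash(snps)),
                       ("reference-only", idx_ref, SnpHash())):
    (aln,) = align_read(idx, read, genome, sh)
    print(f"{label:15s} blocks={tuple(aln.blocks)} clip3={aln.soft_clip3} "
          f"mism_raw={aln.mism_raw} mism_snp_excluded={aln.mism_snp_excluded} "
          f"score={aln.score}")

print("\nThe SNP-aware alignment covers all 75 bases with the mismatch "
      "attributed to the SNP (excluded count 0); the reference-only index "
      "either clips the alternate base or pays an unexplained mismatch.")
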