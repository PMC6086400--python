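# Methods

## The problem

Aligning RNA-seq reads against a single reference genome penalizes every read
that carries a non-reference allele: at a heterozygous SNP the alternate-allele
read pays one mismatch that the reference-allele read does not, so alternate
reads are lost (unmapped, clipped, or mis-placed) at a higher rate. Two
consequences follow. First, the *reference allelic ratio*
refCount / (refCount + altCount) at heterozygous sites is pushed above its
unbiased value of 0.5, corrupting allele-specific expression estimates.
Second, a splice junction whose donor or acceptor dinucleotide is canonical
only under an individual's allele (e.g. a reference GG donor restored to GT by
a G>T SNP) is invisible to aligners that demand canonical motifs in the
reference sequence.

`persplice` addresses both by indexing, next to the reference contigs, short
alternate-allele sequence windows ("SNP-mers") centered on each of the
individual's SNPs, and by consulting the SNP hash both when counting
mismatches and when searching for candidate splice sites.

## SNP-mer extraction

A SNP-mer is a genomic window carrying the alternate allele of its central
SNP. Two schemes:

* **Phased** (`extract_phased_snpmers`): per haplotype and per SNP, a fixed
  window of `k_phased` = 201 bp centered on the SNP, with *all* SNPs of that
  haplotype inside the window substituted, so every window is a literal
  haplotype substring. Homozygous-alternate windows deduplicate across
  haplotypes.
* **Unphased** (`extract_unphased_snpmers`): window length depends on the
  distance `d` to the nearest neighbouring SNP on the same contig:
  `d > k_max` (201 bp) gives a `k_max` window with only the central
  substitution; `k_min <= d <= k_max` gives a window of length `d`;
  `d < k_min` (31 bp) marks a SNP-rich region, where the central SNP is always
  alternate and the `2^(n-1)` alternate/reference combinations of the other
  `n-1` SNPs inside a `k_min` window are sampled `m` = 4 times without
  replacement, seeded per SNP so results are order-independent.

Choices where the scheme was open: the SNP-rich window length is exactly
`k_min` (the smallest window still guaranteeing useful anchors while bounding
the combinatorial blow-up); even-length windows place the SNP at offset
`floor((d-1)/2)`; windows are truncated (not shifted) at contig ends, keeping
the SNP at the clamped center; `m` = 4 covers up to 3 neighbouring SNPs
exhaustively; byte-identical windows are deduplicated before indexing.

## Index and semi-maximal prefix search

The index is a suffix array with an LCP table over the concatenation of the
reference contigs and SNP-mers, separated by sentinel bytes ordered
sentinel < A < C < G < T < N. Construction is a numpy prefix-doubling sort
(O(n log^2 n)) plus Kasai's LCP pass; at the tens-of-kb-to-few-Mb scales this
package targets, construction takes well under a second. N in the reference
never matches any query base (queries encode N as a distinct symbol).

A *semi-maximal prefix search* for a query suffix returns every indexed
position whose exact match is at least `min_match` = 30 bp, each position
reported once at its maximal match length, capped (in suffix-array order) at
64 hits per length. This is implemented as a binary search for the query's
lexicographic position followed by an outward walk over the LCP array, so the
cost is O(|query| log n + hits). Read tiling (`iterative_segment_search`)
repeats the search from the current offset, advancing past the longest match
(or by 1 bp when nothing reaches the threshold); seeds shorter than 18 bp are
discarded as likely spurious.

`align_read` additionally applies a lossless 16-mer presence screen before
scanning an orientation: any exact match of length >= 30 must contain one of
the query's 16-mers sampled at stride 8, so an orientation with no such
k-mer in the index cannot produce seeds and is skipped. The screen disables
itself automatically when `min_match` is set below 30.

## Spliced alignment

Seeds are converted to reference coordinates (SNP-mer hits carry the SNPs
they cover), grouped by diagonal, and merged when contiguous within 2 bp
(gap bases are re-verified when mismatches are recounted). Segments separated
on the genome by an intron-sized gap (`min_intron` = 20 bp to
`max_intron` = 200 kb) are bridged by **double-anchor spliced alignment**:
split points are enumerated over the unaligned read interval plus up to
`min_anchor` = 8 bp of re-assignable anchor overlap; a split is preferred
when its donor/acceptor dinucleotides form a canonical pair
(GT-AG, GC-AG, AT-AC, or their reverse-strand forms CT-AC, CT-GC, GT-AT)
under *either* the reference or the personal alleles. Among admissible splits
the SNP-excluded mismatch count is minimized, with ties broken by reference
GT-AG, then SNP-enabled (polymorphic) GT-AG, then other canonical motifs,
then the leftmost donor. When no canonical split exists the best
noncanonical split is kept and penalized.

Candidates are assembled by chaining segments (up to 3 junctions per read),
extending or soft-clipping the unanchored tails — the clip point maximizes
`extension_length - w_mism * mismatches`, ties preferring the shorter
extension — and scored as

    score = mapped_length - w_mism * mismatches_SNP_excluded
            - w_junc * junctions - w_noncanon * noncanonical_junctions

with `w_mism` = 2, `w_junc` = 1, `w_noncanon` = 4. These weights are package
defaults exposed in `AlignParams`: the method fixes the scoring *criteria*
(mismatches, spliced alignment, mapped length), not the weights. A mismatch
is SNP-attributable iff its reference position is in the SNP hash and the
read base equals the alternate allele; with phased SNPs, attribution
additionally requires the read's alleles over all covered phased SNPs to be
consistent with a single haplotype. Candidates exceeding the mismatch budget
(`ceil(len/25)` SNP-excluded mismatches) or mapping less than half the read
are dropped; all candidates achieving the maximum score are reported (ties =
multi-mapped), and both read orientations compete. Junction strand is
inferred from the motif; motif-ambiguous noncanonical junctions are reported
on '+'. Mates of a pair are aligned independently; single-anchor (one-sided)
spliced alignment and indel alignment are out of scope, so a junction read
whose shorter anchor is below the 30 bp seed threshold is soft-clipped on
that side.

## Allelic-ratio analysis

`count_alleles` tallies the aligned base at each heterozygous SNP over
uniquely mapped primary alignments; soft-clipped bases and intron-spanning
reads never count, and reads matching neither allele go to `otherCount`.
`summarize_ratio_distribution` reports the number of SNPs with at least
`min_reads` = 10 allele-informative reads, the mean ratio, and the biased
(g1) sample skewness `m3 / m2^(3/2)`; a constant sample has skewness 0 by
convention. Multi-mapped and secondary alignments are excluded from counting
(they would double-count); no base-quality floor is applied by default since
simulated qualities are uniform.

## Junction analysis

Junction support counts distinct uniquely mapped alignments containing the
junction with at least `min_anchor` = 8 aligned bases on both sides. A
junction is *polymorphic-gain* when its reference motif is noncanonical but
becomes canonical under an individual's alleles, *loss* for the reverse; a
SNP is a splice-site SNP iff it overlaps the 2 bp donor or acceptor
dinucleotide. Cohort coverage-change tables average raw support (zeros
included — otherwise the "0" bin would be unreachable) separately over
carriers and non-carriers of the splice-site allele and bin the two averages
into {0, (0,2], (2,10], (10,+inf)}; junctions with no carrier or no
non-carrier are skipped and counted separately. Support-threshold grids count
gain junctions with >= {2,5,10} supporting reads in >= {1,2,5,10}
individuals, counting any carrier genotype (het or hom-alt) as a carrier.

## The simulator

`simdata` generates what the analyses need and nothing more: a uniform-random
reference with evenly spaced multi-exon genes (exons 90-220 bp, introns
61-300 bp, boundaries overwritten to GT..AG), heterozygous exonic SNPs,
splice-site plants (gain: the reference donor GT is edited to GG and a G>T
SNP restores it; loss: an acceptor AG>AC SNP corrupts it; the affected intron
is retained on every haplotype lacking the canonical site), and paired-end
reads drawn uniformly over transcripts and haplotypes with fragment length
equal to `insert_len` = 200 bp. The low-error profile plants substitutions at
0.001 per base per haplotype, single-base indel errors at 0.0005 per base,
and sequencing substitution errors at 0.005 per base; the high-error preset
is fivefold each. Reads carrying indel errors are flagged in the ground
truth so analyses that exclude them can do so explicitly. Qualities are
constant 'I' (Q40). Error and indel placement is uniform; no
platform-specific error model, empirical expression distribution, GC bias or
fragment-length distribution is emulated — passing tests therefore
demonstrate algorithmic correctness under idealized sampling, not performance
on real libraries.

## Test and verification sizes

Property and acceptance tests run at sizes where exhaustive oracles are
feasible and sampling noise is controlled: index searches are checked against
a brute-force all-positions scan on <= 5 kb genomes over 1000 fuzzed queries;
alignment scores are checked against an exhaustive <= 1-junction
decomposition oracle on <= 3 kb genomes and 60 bp reads (with a 20 bp seed so
both junction anchors remain seedable); alignment accuracy uses a 100 kb
diploid genome with 20 genes and 200 phased SNPs, where >= 99% of error-free
reads must align uniquely with >= 80% of their aligned bases at the true
coordinates (the 80% rule scores soft-clip-adjacent extensions fairly, since
one-sided junction anchors below the seed threshold are clipped by design);
allelic balance uses 50,000 75 bp reads at base-error 0.005, requiring the
SNP-aware mean ratio within 0.5 +/- 0.02 and the reference-only mean strictly
larger; junction recovery uses an 8-individual cohort with planted gain and
loss junctions; simulator calibration checks empirical frequencies within 3
binomial standard deviations at >= 1e6 bases.

## Known limitations

* No single-anchor spliced alignment: junctions supported by only one
  seedable anchor are soft-clipped, which depresses junction support counts
  symmetrically across alleles.
* No indel alignment: reads with indel errors usually align clipped or not
  at all; germline indels are skipped at VCF parsing.
* Paired-end information does not constrain candidate selection; mates are
  aligned independently and pairing is recorded only in output flags.
* The suffix array is rebuilt per individual (construction is fast at desk
  scale); no compressed/FM index, so genomes beyond tens of Mb are out of
  scope.
* Allelic counting has no base-quality weighting; with real data a quality
  floor (exposed as an option) would be advisable.
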