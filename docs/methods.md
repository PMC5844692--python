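# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); SAM input
(1-based) is converted on read. A read's 5′ end is `start` on the plus
strand and `end − 1` on the minus strand. Collapsed-read copy numbers
travel in the name field as a `-<int>` suffix. The SAM reader is a small
dedicated parser for the headerless subset this pipeline exchanges
(FLAG/POS/MAPQ/CIGAR with M, S, I, D and a single N gap for spliced reads;
NH tags for multiplicity, otherwise multiplicity is inferred by grouping
on read id); BED6's score column doubles as MAPQ for DNA coverage reads.
Abundances are normalized as ppm (per million of a stated denominator:
uniquely mapped reads by default, piRNA-cluster-mapping reads for ox/unox
work) or rpkm (ppm further divided by feature kb).

## EM apportionment of multimappers

Genomic windows (default 5 kb; the last window of a contig may be short)
receive reads by 5′ position — a deliberate choice over fractional overlap
so that each placement selects exactly one window. Window weights start
equal (θᵢ = 1; only weight ratios enter the E step, so any constant works
— normalized and unnormalized weights give identical apportionment). The
E step splits each multimapper's copies across its placements
proportionally to window weights; if every touched window has zero weight
the read splits equally (tie rule). The M step sets θᵢ to the E-step
counts. Convergence is declared when the Manhattan distance between
consecutive count vectors drops below `tolerance_fraction` (default 0.001,
i.e. 0.1% of total read copies); a cap of 1000 iterations guards
non-convergence with a warning rather than an exception. Total read mass
is conserved identically at every iteration. Reads with more than 100
placements are discarded (counted on the grid) to bound incidence lists.

Cluster calling: windows at or above `min_rpkm` (default 10) seed
clusters; adjacent seeds merge across at most `max_gap_windows` (default
1) sub-threshold windows. Strandedness is dual iff 0.5 < Watson/Crick < 2
— the two thresholds are treated as a conjunction, since either inequality
alone is satisfied by almost any cluster — with single-strand degenerate
cases called uni. The transposon antisense fraction classifies each
repeat-overlapping read by the repeat copy it overlaps most; the repeat
fraction is the merged repeat coverage of the cluster interval.
Differential expression between replicate sets uses a per-cluster
two-sided t-test with Benjamini–Hochberg FDR; clusters are flagged at
ratio > 2 or < 0.5 and FDR < 0.1.

## Signature statistics

Spectra accumulate pair weights per lag over 1–30 (30 covers the piRNA
length range); the focal-lag Z score is
(s_focal − mean(background)) / sd(background) with the background being
all other lags (sample sd; an all-equal background gives Z ≡ 0 by
convention). Pair weight is min(copiesᵃ, copiesᵇ) per 5′-position pair —
the product is available as a switch — so a single abundant species
cannot dominate the spectrum.

Ping-pong pairs a plus-strand 5′ end at p with a minus-strand 5′ end at
p + k − 1 (overlap k, inclusive of both ends). The 5′–5′ periodicity
spectrum counts all same-strand pairs at each lag, downstream in
transcript orientation. The 3′–5′ phasing spectrum pairs each 3′ end only
with the *nearest* downstream 5′ end — head-to-tail neighbours — so that
perfectly phased reads place all mass at lag 1 rather than echoing at
multiples of the read length. A one-sided normal tail probability is
attached to Z as a convention; no calibrated null is claimed.

Transposon family age is the length-weighted mean percent divergence of a
family's copies, Σ dᵢℓᵢ / Σ ℓᵢ.

## 3′-end chemistry

Ox/unox ratios are computed on per-million-of-cluster-mapped-reads
normalized counts; using the (methylation-resistant) piRNA pool as the
denominator makes the ratio insensitive to how much total material
survives oxidation. Species that are exact 5′ prefixes of any 23–35-nt
species in the supplied piRNA set are removed first, since piRNA
degradation fragments of siRNA length would otherwise inflate the
methylated tail of the distribution. The median is reported over species
with at least 5 unoxidized copies (config knob) to suppress ratio noise.

Tail calling walks the read 5′→3′ against the genome at its placement
(T and U equivalent; minus-strand placements are complemented) and takes
the longest matching prefix as templated; the remainder is the tail,
classed none / mono-U / oligo-U / A / other. A minimum anchor of 16
templated nt guards against spurious long tails from bad placements —
reads failing it raise rather than being called tailed.

Trimming is operationalized as 18–19-nt reads sharing contig, strand and
5′ position with a ≥ 20-nt species. Duplex reconstruction pairs a plus
species at [s, e) with a minus species at [s − 2, e − 2) — the
two-nucleotide 3′ overhang at both ends — after aggregating copies per
placement; the guide is the more abundant strand (the thermodynamic
definition would need pairing energies, which alignment data do not
carry), and the summary reports the fraction of duplexes at
guide/passenger ≥ 2, the median and the mean.

## Sex linkage

Coverage is per-base depth (mapped bases / contig length) over reads with
MAPQ ≥ 20, divided by the median across contigs. Labels are pure
threshold functions of the M:F ratio: Z above 1.5, W below 0.5, autosome
between, with zero female coverage treated as an infinite ratio (Z), and
contigs below 0.05× median in both sexes called ambiguous rather than
forced to W. The dosage summary is a ratio of medians over expressed
genes (abundance > 0), Z-linked versus autosomal.

## Splicing

Junctions come from single-gap alignments grouped by (contig, donor,
acceptor, strand). The entropy filter uses the Shannon entropy (bits) of
spanning-read leftmost start positions; ≥ 10 reads and ≥ 2 bits are both
required (the filters commute). The unspliced denominator counts ungapped
reads crossing the donor with at least 3 nt on each side — the efficiency
definition fixes only the numerator and denominator concepts, so the
overlap rule is stated here explicitly. Efficiency is spliced/unspliced;
fold suppression is median(outside clusters)/median(inside), optionally
split by the host cluster's strandedness.

## The synthetic-data generator

All outputs are deterministic given the seed. Count noise is Poisson
(emission, coverage) or multinomial (library resampling) — the simplest
models consistent with count data. The reference scenario is a 500-kb
genome (three 100-kb autosomes, one Z, one W) with four planted clusters:
a uni-strand autosomal cluster, a dual-strand autosomal cluster, a
uni-strand (Crick) Z cluster, and a dual-strand cluster covering 90% of
the W contig. Clusters emit ~2000 read copies/kb over ~20 species/kb;
the inter-cluster background is sparse single-copy species at 0.1/kb,
mirroring the near-zero inter-cluster piRNA levels of real ovary
libraries. Defaults: 1U bias 0.7 (a categorical first-nucleotide choice),
30% ping-pong pairs within dual-strand clusters (opposite-strand partners
with exact 10-nt 5′ overlap), 30% multimapping species with one or two
extra placements in another cluster or at a background decoy locus,
≥ 97.5% main-strand purity for uni-strand clusters. Transposon copies
(1 kb, divergence ~ N(10, 5)% clipped to [0.1, 60]) cover ~60% of cluster
bases, with extra repeat load on W.

The viral replicon (segments of 3000 and 2000 nt) emits 20-nt reads tiled
end-to-end at the configured phasing fidelity (register slips of 1–19 nt
otherwise). Tails are appended at a per-read rate of 0.0669 with
composition U 0.496 / A 0.252 / C 0.126 / G 0.126; the genomic base
immediately after a tailed read is mutated away from the tail's first
nucleotide *before* downstream reads are drawn, so every planted tail is
unambiguously non-templated and exactly recoverable by the
longest-prefix rule. Trimmed reads (rate 0.0105) are binomially split
from each site's copies as 18–19-nt 5′ prefixes, so the copy-weighted
short-read fraction matches the rate in expectation.

Library pairs co-sample the siRNA species with a fully methylated piRNA
pool in one multinomial per library; oxidation divides unmethylated
species' weights by the depletion factor (default 5), and the piRNA pool
counts become each library's cluster-mapped denominator — which is
exactly why the expected ox/unox ratio is 1/depletion for unmethylated
and 1 for methylated species, independent of how much the oxidized
library shrank. DNA coverage draws Poisson read counts per contig at
2×/1×/0× the per-haplotype rate for A/Z/W by sex, with ~10% of reads
below MAPQ 20 everywhere, a burst of low-MAPQ cross-mapped reads on the
male W, and an 11% confidently-mapped male W residual (so the W ratio
lands near 0.11 rather than identically zero). Junction reads cycle
spliced-read start offsets round-robin over n distinct positions (default
6), planting offset entropy near log₂ n; the number of spliced reads is
binomial in the planted spliced fraction.

Not emulated: sequencing errors, adapters, quality scores, GC or ligation
bias, chimeric reads, genuine repeat-driven ambiguous alignment (the
multimapper structure is planted, not produced by an aligner), and
genome-scale contig counts. Passing recovery tests therefore demonstrates
the correctness of the statistics and the EM machinery under the planted
model, not robustness to alignment artifacts in real libraries.

## Problem sizes

The test suite and the acceptance script run the reference scenario at
desk scale: 500-kb genomes, ~10⁵–10⁶ read copies collapsed into a few
thousand species, ox/unox depth 10⁵, coverage 40×, junction depth 10³,
10–20 seeds per recovery check. These sizes put every recovered quantity
well inside the tolerances asserted (binomial/Poisson 3σ, 10–15%
relative for medians of ratios) while keeping the full suite under half
a minute.

## Known limitations

- The EM fixed point is compared against an independently coded
  brute-force iteration along the same trajectory; uniqueness of the
  fixed point for pathological incidence structures is not proven.
- Guide-strand identity is abundance-based; thermodynamically defined
  guides can differ for near-symmetric duplexes.
- The entropy filter's offset definition (leftmost alignment start)
  follows the common PCR-duplicate heuristic; UMI-aware deduplication is
  out of scope.
- Dosage ratios use ratio-of-medians over expressed genes, not a full
  dosage-compensation model.
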