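# Methods

This note documents the models, estimators, numerical choices and
limitations of the package, in the order the pipeline applies them.

## Study design and data model

The analysis assumes two groups of haploid genomes ("SB" and "Sb", default
8 per group) sampled as cross-group sibling pairs: each colony contributes
one SB and one Sb brother, so every individual's closest relative is in the
other group. Genotypes are haploid calls in a VCF with a site-level
confidence (`SITE_CONF`, INFO) and per-sample genotype confidence and
called-allele coverage (`GT_CONF`, `COV`, FORMAT), the annotations a de
Bruijn graph bubble caller emits. The reference genome is treated as an SB
individual's assembly, so the SB group's consensus at fixed-difference
sites usually equals the reference.

## Variant and STR filters

A site is retained when `SITE_CONF > 15` and, for every sample in scope,
the call is present with coverage ≥ 1 and `GT_CONF` above a depth-class
threshold (> 10 for low-coverage samples, > 2 for high-coverage ones; one
sample per group is high-coverage in the default design). Filters run in
whole-set mode for between-group statistics and per-group mode for
within-group diversity, so genotype quality in one group never censors the
other group's diversity estimate. STR loci are kept when the reference
repeat-unit count strictly exceeds 9 / 5 / 4 for period 1 / 2 / ≥3 ("larger
than" read strictly; a flag switches to inclusive), and calls when every
in-scope sample has Q ≥ 0.25, ≥ 2 supporting reads and ≤ 25 total reads
(the coverage maximum read inclusively).

## Windows

Windows are defined over accessible (non-N) positions: each window spans
exactly `size` non-N bases, stretching physically across assembly gaps, and
successive windows begin `step` accessible bases apart. Terminal partial
windows are flagged and excluded from genome-wide means but retained in
scans. Defaults: a 30 kb / 10 kb sliding scan, a 10 kb tiling for summary
means, and a 30 kb tiling for region calling.

## F<sub>ST</sub>

Multilocus F<sub>ST</sub> is a two-level variance decomposition of haploid
allele-presence indicators (Weir–Cockerham style). Per site and allele,
with group frequencies p₁, p₂, sizes n₁, n₂, N = n₁+n₂ and
n_c = (N − (n₁²+n₂²)/N):

* MSB = n₁(p₁−p̄)² + n₂(p₂−p̄)² (df = 1),
* MSW = [n₁p₁(1−p₁) + n₂p₂(1−p₂)] / (N−2),
* a = (MSB − MSW)/n_c, b = MSW.

Components are summed over alleles and sites; F<sub>ST</sub> = Σa/Σ(a+b).
A window with Σ(a+b) = 0 is undefined (NaN), never 0 — consumers (region
calling, summaries) treat NaN as a run-breaker / drop it from means.
Multiallelic sites are handled naturally by the per-allele decomposition.
Sibling pairing makes background values slightly negative: a pair-private
variant contributes MSB < MSW.

## Diversity

π per group = Σ_sites (n/(n−1))(1 − Σᵢpᵢ²) / accessible bp, the unbiased
mean pairwise difference rate; sites with fewer than two calls are skipped.
All variant classes (SNPs and indels) count toward π; fixed differences are
tallied with SNPs and indels separate.

## Scaffold placement

Scaffolds are placed on linkage groups from RAD-style markers of several
family maps: scaffolds supported by a single sparse single-queen family map
(< 4 markers) are dropped; scaffolds with markers on ≥ 2 linkage groups are
split into the per-group marker ranges (interleaved ranges are an
irresolvable chimera and raise); segments are ordered within a linkage
group by mean marker cM, with orientation from the sign of the cM–bp
correlation ("unknown" for single markers or ties — propagated, never
guessed). This mean-cM placement replaces a genetic-algorithm orderer
because the downstream statistics depend only on segment-to-linkage-group
assignment and coarse order. Internally all segment coordinates are 0-based
half-open; VCF/GFF positions are 1-based and converted at one boundary.

## Coding divergence

Gene models are filtered before divergence estimation: genes tagged partial
or modified-RefSeq, with N in the CDS, CDS length not a multiple of 3,
mitochondrial code (transl_table=5), or any retained indel overlapping the
CDS in any sample are removed. Consensus CDS pairs substitute each group's
fixed allele into the reference CDS (reverse-complemented into coding
orientation for minus-strand genes). Divergence is Nei–Gojobori (1986)
counting: per-codon synonymous site fractions (changes to stop codons count
as nonsynonymous), sites averaged over both sequences so N + S equals the
CDS length; codons differing at multiple positions average equally over
minimal mutation paths that avoid stop codons (all paths if none avoids
them); Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3), undefined (flagged)
at p ≥ 3/4; dN/dS is NaN when dS = 0. The McDonald–Kreitman contrast uses
the same effect classification for SNPs fixed between groups vs polymorphic
among SB within the same genes, tested as a Yates-corrected 2×2 χ²
(continuity correction is the default throughout because it is the variant
that matches the published statistic on the published counts). The
genome-wide dN/dS comparison against an externally supplied background
distribution uses a Wilcoxon signed-rank test against the background median
(the background carries no gene pairing, so the distribution is reduced to
its median) with a rank-sum test reported alongside.

## Strata scan

The scan evaluates every contiguous span of ≥ `min_span` (default 30)
genes, Welch-testing the span's per-gene divergence against all other
genes, and takes the qualifying span (mean strictly below the complement's)
with the smallest two-sided p. Span length is bounded so the **complement
also keeps at least `min_span` genes** (at least 2 when fewer than
2×min_span genes exist). This bound is a deliberate design choice: with
integer substitution counts, an unbounded scan lets spans whose 2–3-gene
complement has near-zero variance produce p ≈ 10⁻⁵⁰ in observed and
simulated scans alike, which keeps the empirical p calibrated but destroys
all power to see a real stratum; requiring a complement of stratum size
removes the degeneracy symmetrically (measured: planted-stratum detection
goes from 0/20 to 19/20 replicates, null calibration stays uniform).

Significance comes from a Poisson null: per simulation, gene substitution
counts ~ Poisson(λ × coding length) with λ defaulting to 1/3000 per coding
bp, converted to per-gene rates and scanned identically; the empirical p is
the fraction of simulations whose minimal p is ≤ the observed one (ties
count as stronger). Observed data are scanned on the same rate scale
(fixed differences per coding bp; dS is accepted as an alternative input
column on the same footing). The degenerate all-equal profile yields "no
qualifying span" and empirical p = 1.

## Region inference

The supergene region is the maximal run of ≥ 2 consecutive non-overlapping
windows with F<sub>ST</sub> > 0.25 (thresholds exposed as flags; the
0.6–1.0 range seen inside real regions is descriptive, not a rule).
Unmapped scaffolds join the region when ≥ 1 window (flag
`min_qualifying_windows`) has F<sub>ST</sub> > 0.75 *and* > 25 fixed
differences per 30 kb. Permutation tests reallocate the 16 labels (group
sizes preserved; optionally restricted to mixed-genotype groupings) and use
the add-one Monte-Carlo convention p = (1+#{null ≥ obs})/(n+1), so p = 0 is
impossible and the true labelling guarantees p ≥ 1/(n+1). Region-size
extrapolation multiplies the in-analysis region fraction by externally
supplied genome-size bounds; the analysed-bp denominator is an explicit
argument, never hard-coded.

## Synthetic data generator

The generator is the package's test substrate and defines the conditions
every recovery claim is made under. It emulates marginal site patterns, not
genealogies: variant sites are placed by disjoint per-class binomial draws
over non-N positions, with classes
fixed-difference (region, default 1.4×10⁻³/bp), SB-only and Sb-only
polymorphism (region, calibrated to π = 6.7×10⁻⁴ and 1.3×10⁻⁶), shared
polymorphism (background, calibrated to π = 8.2×10⁻⁴ over the pooled 16
samples — a random subgroup inherits the same expected π because the
unbiased estimator is subsampling-invariant), and optional pair-private
variants (one SB and their Sb brother; default 3×10⁻⁴/bp when enabled,
about half the shared pool's doubleton density, as full-sib pairing
implies) that reproduce the negative background F<sub>ST</sub> of the
paired design. Within-group minor allele counts follow a 1/i weighting
(i = 1..n/2), which keeps the π ↔ site-density mapping analytic
(density = π / E[h]); the real site-frequency spectrum is unknown to the
generator and this choice is a stand-in, not an inference.

Genes (default 320 of 900 bp — about the real annotation's 49 genes/Mb —
on either strand, CDS rewritten with stop-free codons) intersect the
variant layer: fixed differences inside a CDS choose their alternate base
codon-aware, nonsynonymous with probability `frac_nonsyn_fixed` (0.47, the
published nonsynonymous fraction of fixed coding SNPs) where the codon
allows it, and the planted per-gene (syn, nonsyn) counts go into the truth
record. A configurable number of genes receives an in-CDS indel to
exercise the gene filter. N-gaps are contiguous 2–10 kb blocks (so the
window-stretching logic is exercised), never scattered singletons.
Confidence fields are drawn so small configurable fractions fail each
filter (defaults 0.5% site-level, 0.05% per-sample genotype, 0.02% zero
coverage): enough to exercise every rule while keeping the filtered
density within the recovery tolerances. The real study discarded a third
of raw calls, but those removals reflect caller-specific error modes this
generator does not emulate, so its defaults are deliberately mild.

What passing recovery tests therefore shows: the estimators correctly
recover marginal densities, frequencies and region geometry under the
design's sample sizes and the filters' censoring. What they do not show:
robustness to linkage disequilibrium, coverage-correlated genotyping error,
reference bias, or misassembly — none of which the generator produces.

## Problem sizes and tolerances

Tests and the acceptance script run on a 6.5 Mb three-scaffold genome with
a 1 Mb planted region (the package's chosen desk-scale study): large enough
that background π has ≈1% sampling error (the recovery claim is 5%) and the
region holds ~50 genes. The strata null-calibration check uses 1,000 outer
replicates of 200 inner simulations on 120 genes of 0.9–3 kb; the power
check plants a 30-gene λ/10 stratum among 400 genes of 1.5 kb (100
replicates, 100 inner simulations — the planted signal sits orders of
magnitude below the null's minimal p, so inner resolution is not
limiting). Oracle agreement for F<sub>ST</sub> is asserted to 1×10⁻¹²
against an independent brute-force ANOVA; exact tests to 1×10⁻¹² against
full enumeration on all 2×2 tables with total ≤ 12. Pipeline determinism
is exact under fixed seeds (byte-identical generator output, seeded
simulations and permutations).

## Known limitations

* The F<sub>ST</sub> estimator is one specific variance-components variant;
  other estimators differ at low sample sizes (they agree at fixation).
* NG86 with equal path weighting and Jukes–Cantor correction is the only
  divergence estimator; at the divergences this system shows (dS ~ 0.002)
  estimator choice is immaterial, but the interface leaves room for a
  second counting method.
* The strata scan tests a single candidate stratum (the lowest-divergence
  span); it is not a multi-changepoint segmentation.
* Consensus building assumes the reference individual belongs to the SB
  group; a reference from the other group would only swap the pair.
* The region boundary is resolved to one calling window (30 kb); summary
  statistics near the boundary inherit that resolution.
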