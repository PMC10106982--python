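# Methods

This note documents the models and procedures `cinpipe` implements, the
defaults it ships, and what the synthetic-data generator does and does
not emulate.

## Read-depth karyotyping

**Model.** A haploid strain sequenced to mean per-bp depth λ/b (bin size
b) yields bin counts whose expectation is proportional to the local copy
number. Copy number is estimated per chromosome, not per bin, from the
depth of fixed-length telomere-proximal windows, which removes the
dependence of a whole-chromosome mean on chromosome length.

**Procedure.**

1. *Telomere-window depth* — mean per-bp depth over the first and last
   `telomere_window` bp of each chromosome (default 15,000 per end; a
   single-end mode is available). Bins partially overlapping a window
   contribute pro rata. If the two windows would meet or overlap
   (2·window ≥ chromosome length), the whole chromosome is used instead.
   Averaging both ends was chosen for symmetric sampling; which end the
   original analysis used is not determinable, so both conventions are
   exposed.
2. *Reference depth* — per-chromosome values are ranked ascending and
   the ranks ⌈n/4⌉+1 … ⌈n/2⌉ (5–8 of 16) are averaged (mean by default,
   median selectable). Because a disomy roughly doubles a chromosome's
   value, up to ⌈n/4⌉ doubled chromosomes land entirely in the upper
   quartiles and leave the reference unchanged; this is tested as an
   invariant.
3. *Disomy call* — normalized copy number strictly greater than
   `disomy_threshold` (default 1.5). The inequality is strict: a value
   of exactly 1.5 is euploid.
4. *Segmental amplification* — counts are re-binned to
   `segment_bin_size` (default 4,000 bp) and divided by the reference
   per-bp depth; maximal runs of at least `min_segment_bins` (default 5)
   consecutive bins with ratio > `segment_ratio_threshold` (default 1.5)
   become segments. The original study identified segments visually, so
   the run-length rule is this package's own explicit criterion, and all
   three constants are surfaced in `KaryotypeParams`. A segment covering
   every bin of its chromosome is a whole-chromosome disomy seen at
   segment resolution and is marked `spans_chromosome`.
5. *Exclusion flag* — a strain is flagged when any non-spanning segment
   reaches `large_segment_length` (default 100,000 bp). "Large" was not
   quantified in the source analysis; 100 kb is a declared choice.

Every statistic in steps 1–5 is a ratio of depths, so multiplying all
bin counts by any positive constant changes no call (scale invariance,
tested exactly).

**Coordinates.** Depth bins are 0-based half-open (bedGraph convention);
gene annotation is 1-based inclusive (GFF3). Conversions live only in
the I/O helpers. A segment that includes the trailing short bin of a
chromosome has its end clipped to the chromosome length, so
`n_bins × bin_size = end − start` holds exactly for interior segments.

## Variant workflow

Records are single-nucleotide substitutions carrying (chrom, pos, ref,
alt, qual, depth); indels and multi-allelic records are skipped at parse
time with a warning. Filtering keeps qual strictly greater than
`min_qual` (default 95) and depth on the admissible side of
`depth_cutoff` (default 300). The phrase "read depth cutoff" is
directionally ambiguous; the default mode `max` (keep depth ≤ 300,
guarding against collapsed-repeat pileups) is a declared choice and mode
`min` is selectable. Records lacking DP fail closed unless
`missing_depth="pass"`.

Ancestor subtraction removes evolved records whose (chrom, pos, alt) key
occurs in the parent strain; ref is validated against the genome rather
than used for matching. Effect classification locates the codon on the
gene's own strand, substitutes the (strand-corrected) alternate base and
translates both codons with the standard nuclear code: identical amino
acid → silent, stop gained → nonsense, anything else — including
stop-loss, for which the vocabulary has no separate class — missense.
Genes are single-exon CDSs, which makes the classifier contract exact;
multi-exon genes are out of scope (introns are rare in this organism).
The classifier is verified exhaustively against an independent oracle
that rebuilds the whole mutant chromosome and diffs the full translated
proteins, for every possible substitution of a 10 kb fixture genome with
genes on both strands.

## Cohort statistics

Enrichment is the exact hypergeometric upper tail P(X ≥ k) for k
category hits among n mutated-gene hits, category size K, universe N
(defaults mirroring the yeast annotation: N = 6,002, K = 874). The
default counting mode is per-hit — a gene mutated independently in two
strains counts twice, matching mutation-level tallies — with a per-gene
deduplicating mode available. No multiple-testing correction is applied
by the core test; a Benjamini–Hochberg helper is provided for batches.
Displayed percentages truncate to the shown precision (874/6,002 prints
as 14.5%), matching the reporting convention of the source figures.

Aneuploidy summaries (mean disomies per strain, per-chromosome
aneuploidy frequency) are computed over non-excluded strains only.
Transmission fidelity is the selective/nonselective colony-count ratio,
reported unclamped (values > 1 arise from plating noise and are logged).
The unpaired t-test defaults to Student's pooled-variance form, the
common default of graphing software, with Welch selectable.

## Image quantification

Line scans sample bilinearly interpolated intensities along a segment,
averaged over a perpendicular width (default 3 px; the original width is
unstated). Profiles are fit with A·exp(−(x−µ)²/2σ²) + c by
Levenberg–Marquardt least squares with moment-based initialization and
σ bounded in (0.5 px, profile length); non-convergence is flagged and
the AUC (= A·σ·√(2π), the background-free integrated intensity) is then
omitted, never silently substituted. For the noisy-recovery checks the
profiles span 40 px sampled at 0.2 px; at coarser sampling the
information content of a σ = 2 px peak is too low for 5%-accurate AUC
recovery regardless of estimator, so the denser sampling is the
package's default design for this measurement.

Circular ROI intensity sums the inner disk and subtracts the annulus
mean times the inner pixel count; uniform images cancel exactly and
negative values are reported as-is. Growth area is the percentage of
pixels ≥ threshold inside a measurement circle. Colony counting labels
the thresholded image with 8-connectivity and gates components by pixel
area; the min/max size gate is explicit because particle-analyzer
behaviour varies with settings.

## Synthetic data

The generator emulates the study's inputs at desk scale: 16 chromosomes
of 200–400 kb (scaled down from the 230 kb–1.5 Mb genome for runtime),
gene density 0.35 genes/kb with 300–1,500 bp single-exon CDSs on both
strands, Poisson bin counts at λ = 100 reads/kb-bin by default (the
study does not state per-strain depth; λ is a free parameter), disomies
and segmental events planted as integer copy numbers, and variant
attributes drawn to straddle the quality/depth filters. A
negative-binomial noise option (variance m + m²/dispersion) supports
robustness checks. Images are sums of isotropic Gaussians or uniform
disks on flat backgrounds with additive Gaussian noise, clipped at zero.

All randomness descends from one root seed: each generator derives an
independent child stream from (seed, label), so outputs are bit
reproducible and adding a generator never perturbs existing streams.

**What the simulations do not capture:** GC and mappability bias,
read-level error models, clonal heterogeneity (fractional copy numbers),
diploid genotypes, multi-exon genes, optical blur/PSF structure and
uneven illumination. Passing the recovery tests therefore demonstrates
correctness of the estimators under their stated noise models, not
robustness to every artefact of real sequencing or microscopy data.

## Problem sizes

Recovery checks use 100 simulated strains (16 chromosomes, λ = 50
reads/bin) for karyotyping, ~30,000 substitutions for the classifier,
200 profiles for the Gaussian fit, 50 plates for colony counting, and
100 cohorts of 50 strains for enrichment power — sizes at which the
binomial uncertainty of the reported rates is a few percent while a full
run stays in the minutes range on one core.
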