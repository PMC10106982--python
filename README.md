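# cinpipe

Analysis toolkit for tracking how haploid budding-yeast populations adapt
to chromosomal instability (CIN). When the chromosomal passenger complex
is crippled, cells missegregate chromosomes at high rates; evolving
populations first accumulate specific whole-chromosome aneuploidies
(disomies in a haploid), then acquire suppressor point mutations that
relieve the need for them. `cinpipe` implements the computational side of
that study design as a reusable, tested library:

- **Read-depth karyotyping** — call per-chromosome copy number from
  binned whole-genome sequencing coverage, and detect segmental
  amplifications on a coarser binning.
- **Mutation identification** — filter variant records, subtract the
  ancestral (parent-strain) variant set, and classify surviving
  substitutions as noncoding / silent / missense / nonsense.
- **Cohort statistics** — CIN gene-set enrichment (exact hypergeometric
  test), aneuploidy burden summaries, minichromosome transmission
  fidelity, unpaired t-tests.
- **Image quantification** — perpendicular line scans with Gaussian
  fitting, circular-ROI intensities with annulus background subtraction,
  thresholded growth areas, colony counting.
- **Synthetic data** — every input (genome FASTA/GFF3, bedGraph depth,
  VCFs, spindle/plate images) can be generated with known ground truth,
  so the whole pipeline is testable end to end without any download.

## The model

Karyotype calling normalizes depth so chromosomes of different lengths
are comparable. For chromosome *i*, let *d<sub>i</sub>* be the mean
per-bp read depth over the 15 kb windows closest to each telomere. The
euploid reference *r* is the mean of the *d<sub>i</sub>* whose ascending
rank falls in the second-lowest quartile (ranks 5–8 of 16) — disomic
chromosomes inflate the upper quartiles and cannot bias it. The
normalized copy number is *c<sub>i</sub>* = *d<sub>i</sub>* / *r*, and a
chromosome is called disomic when *c<sub>i</sub>* > 1.5 (strict).
Segmental amplifications are maximal runs of ≥ 5 consecutive 4 kb bins
with depth ratio > 1.5; strains with a sub-chromosomal run ≥ 100 kb are
flagged for exclusion from cohort aneuploidy statistics.

Variant records pass the filters when quality > 95 and read depth ≤ 300
(the cutoff side is configurable). Effects are classified on the gene's
own strand with the standard nuclear code. Enrichment of *n* mutated
genes with *k* hits in a category of size *K* within a universe of *N*
genes is the hypergeometric upper tail
P(X ≥ k) = Σ<sub>i≥k</sub> C(K,i)·C(N−K,n−i)/C(N,n).
Fluorescence line scans are fit with A·exp(−(x−µ)²/2σ²) + c and reported
as the area under the curve, AUC = A·σ·√(2π).

## Worked example

`examples/01_simulate_and_karyotype.py` plants disomies of chr03 and
chr11 plus a 100 kb segmental amplification on chr07, simulates Poisson
bin counts at λ = 100 reads/kb, and calls the karyotype:

```
chrom   copy_number  disomic
chr01       1.003  False
chr02       1.065  False
chr03       2.065  True
...
called disomic: ['chr03', 'chr11'] (planted: chr03, chr11)
segmental: chr07:60000-160000  mean ratio 2.01
large-segmental exclusion flag: True
```

Copy numbers sit near 1.0 for euploid chromosomes and near 2.0 for the
planted disomies; the chr07 event is reported as segmental (it does not
span the chromosome) and, at 100 kb, trips the exclusion flag.
`examples/03_cohort_statistics.py` prints the CIN-category share of the
yeast gene universe (874 of 6,002 genes = 14.5%) and an enrichment test
on a simulated cohort mutating category genes at 3× background:

```
enrichment: 26/83 mutated genes in category (31.3%), hypergeometric p = 7.28e-05
```

The other examples cover variant annotation, image quantification and
the full file-based pipeline (`cinpipe simulate --out-dir run --seed 1`
from the shell does the same).

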