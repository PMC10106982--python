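"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: the effect oracle
rebuilds the whole mutant chromosome, re-extracts the full CDS and
translates both proteins end to end.
"""

from Bio.Seq import Seq

from cinpipe.genome import GenomeModel, revcomp


def classify_by_full_translation(genome: GenomeModel, chrom: str, pos: int, alt: str) -> str:
    """Effect of a substitution by full-CDS translation diff."""
    gene = genome.gene_at(chrom, pos)
    if gene is None:
        return "noncoding"
    seq = genome.chromosomes[chrom]
    mutant = seq[: pos - 1] + alt + seq[pos:]
    ref_cds = seq[gene.start - 1 : gene.end]
    alt_cds = mutant[gene.start - 1 : gene.end]
    if gene.strand == "-":
        ref_cds, alt_cds = revcomp(ref_cds), revcomp(alt_cds)
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    if ref_prot == alt_prot:
        return "silent"
    diff = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    i = diff[0]
    if alt_prot[i] == "*" and ref_prot[i] != "*":
        return "nonsense"
    return "missense"
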