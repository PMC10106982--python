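"""Variant filtering, ancestor subtraction and coding-effect classification.

Evolved strains are compared against their ancestor: records are filtered
on quality (strictly > 95 by default) and read depth (cutoff 300), the
ancestral variant set is subtracted by (chrom, pos, alt) identity, and the
surviving single-nucleotide substitutions are classified against the gene
annotation as noncoding, silent, missense or nonsense using the standard
nuclear codon table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .genome import Gene, GenomeModel, STOP_CODONS, revcomp

log = logging.getLogger(__name__)

EFFECTS = ("noncoding", "silent", "missense", "nonsense")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide substitution with its call attributes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"only SNVs supported: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used for ancestor subtraction: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    record: VariantRecord
    gene_id: str | None
    codon_index: int | None  # 0-based codon number within the CDS
    codon_change: str | None  # e.g. "AAA>GAA", on the gene's strand
    aa_change: str | None  # e.g. "K2E" (1-based residue number)
    effect: str

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if (self.effect == "noncoding") != (self.gene_id is None):
            raise ValueError("effect 'noncoding' iff no gene context")


@dataclass
class FilterParams:
    """Quality/depth filter thresholds.

    ``min_qual`` is strict (a record at exactly the threshold is removed).
    ``depth_mode`` sets which side of ``depth_cutoff`` is admissible:
    ``"max"`` keeps depth <= cutoff (guards against collapsed repeats),
    ``"min"`` keeps depth >= cutoff.  The original analysis left the
    direction ambiguous; both are provided, default ``"max"``.
    """

    min_qual: float = 95.0
    depth_cutoff: int = 300
    depth_mode: str = "max"

    def __post_init__(self) -> None:
        if self.min_qual <= 0 or self.depth_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if self.depth_mode not in ("max", "min"):
            raise ValueError("depth_mode must be 'max' or 'min'")


def filter_variants(
    records: list[VariantRecord], params: FilterParams | None = None
) -> list[VariantRecord]:
    """Keep records with qual strictly above the minimum and admissible depth."""
    params = params or FilterParams()
    if params.depth_mode == "max":
        ok = lambda r: r.qual > params.min_qual and r.depth <= params.depth_cutoff
    else:
        ok = lambda r: r.qual > params.min_qual and r.depth >= params.depth_cutoff
    return [r for r in records if ok(r)]


def subtract_ancestor(
    evolved: list[VariantRecord], ancestor: list[VariantRecord]
) -> list[VariantRecord]:
    """Evolved records absent from the ancestor, by (chrom, pos, alt), in order."""
    ancestral = {r.key for r in ancestor}
    return [r for r in evolved if r.key not in ancestral]


def classify_effect(v: VariantRecord, genome: GenomeModel) -> AnnotatedVariant:
    """Classify a substitution as noncoding / silent / missense / nonsense.

    The codon carrying the variant is located on the gene's own strand
    (reverse complement for '-' genes) and both reference and mutant
    codons are translated with the standard nuclear code.  Stop-gain is
    nonsense; unchanged amino acid is silent; everything else, including
    stop-loss, is missense.
    """
    ref_base = genome.base_at(v.chrom, v.pos)
    if ref_base != v.ref:
        raise ValueError(
            f"ref mismatch at {v.chrom}:{v.pos}: record {v.ref}, genome {ref_base}"
        )
    gene = genome.gene_at(v.chrom, v.pos)
    if gene is None:
        return AnnotatedVariant(v, None, None, None, None, "noncoding")

    if gene.strand == "+":
        offset = v.pos - gene.start
        alt_on_cds = v.alt
    else:
        offset = gene.end - v.pos
        alt_on_cds = revcomp(v.alt)
    if not 0 <= offset < gene.length:  # pragma: no cover - guarded by gene_at
        raise ValueError(f"CDS bookkeeping inconsistent for {gene.gene_id}")
    codon_i, within = divmod(offset, 3)
    cds = genome.cds_sequence(gene)
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = ref_codon[:within] + alt_on_cds + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "silent"
    elif alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
        effect = "nonsense"
    else:
        effect = "missense"
    return AnnotatedVariant(
        record=v,
        gene_id=gene.gene_id,
        codon_index=codon_i,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{codon_i + 1}{'X' if alt_aa == '*' else alt_aa}",
        effect=effect,
    )


def annotate_variants(
    records: list[VariantRecord], genome: GenomeModel
) -> list[AnnotatedVariant]:
    return [classify_effect(v, genome) for v in records]


def select_nonsynonymous(annotated: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep protein-altering variants: missense and nonsense."""
    return [a for a in annotated if a.effect in ("missense", "nonsense")]


# ------------------------------------------------------------------------ I/O
VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: list[VariantRecord], path: str | Path) -> None:
    """Write a minimal VCF v4.2 with DP carried in INFO."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}\t.\tDP={r.depth}\n"
            )


def read_vcf(
    path: str | Path, missing_depth: str = "fail"
) -> list[VariantRecord]:
    """Read SNV records from a VCF.

    Indels and multi-allelic records are skipped with a warning.  Records
    lacking DP are dropped (fail-closed) unless ``missing_depth="pass"``,
    in which case depth 0 is assigned.
    """
    from pysam import VariantFile

    out: list[VariantRecord] = []
    dropped = {"indel": 0, "multiallelic": 0, "no_depth": 0}
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                dropped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1:
                dropped["indel"] += 1
                continue
            dp = rec.info.get("DP")
            if dp is None:
                if missing_depth != "pass":
                    dropped["no_depth"] += 1
                    continue
                dp = 0
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    depth=int(dp),
                )
            )
    for kind, n in dropped.items():
        if n:
            log.warning("%s: dropped %d %s record(s)", path, n, kind)
    return out


def annotation_table(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.record.chrom for a in annotated],
            "pos": [a.record.pos for a in annotated],
            "ref": [a.record.ref for a in annotated],
            "alt": [a.record.alt for a in annotated],
            "qual": [a.record.qual for a in annotated],
            "depth": [a.record.depth for a in annotated],
            "gene": [a.gene_id or "." for a in annotated],
            "codon_change": [a.codon_change or "." for a in annotated],
            "aa_change": [a.aa_change or "." for a in annotated],
            "effect": [a.effect for a in annotated],
        }
    )
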