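"""Genome model: chromosome sequences plus single-exon gene annotation.

The :class:`GenomeModel` is the coordinate authority for every downstream
module — variant-effect classification, depth-track binning and input
validation all resolve positions against it.  Gene coordinates follow the
GFF3 convention (1-based, inclusive); depth bins elsewhere follow the
bedGraph convention (0-based, half-open).  Conversions are localized in the
I/O helpers here.
"""

from __future__ import annotations

import io
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A single-exon protein-coding gene.

    ``start``/``end`` are 1-based inclusive chromosome coordinates of the
    CDS; for ``strand == '-'`` the coding sequence is the reverse
    complement of the genomic slice.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid gene interval {self.gene_id}: {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeModel:
    """Chromosome sequences and gene intervals.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to its sequence (uppercase A/C/G/T).
        Insertion order defines the canonical chromosome order.
    genes
        Non-overlapping single-exon CDS intervals.
    """

    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    _index: dict[str, tuple[list[int], list[Gene]]] = field(
        default=None, repr=False, compare=False
    )

    # ------------------------------------------------------------------ basics
    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        try:
            return len(self.chromosomes[chrom])
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.chromosomes[chrom]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return seq[pos - 1]

    # ------------------------------------------------------------- gene lookup
    def _ensure_index(self) -> None:
        if self._index is None:
            idx: dict[str, tuple[list[int], list[Gene]]] = {}
            for chrom in self.chromosomes:
                genes = sorted(
                    (g for g in self.genes if g.chrom == chrom),
                    key=lambda g: g.start,
                )
                idx[chrom] = ([g.start for g in genes], genes)
            object.__setattr__(self, "_index", idx)

    def gene_at(self, chrom: str, pos: int) -> Gene | None:
        """Gene whose CDS contains the 1-based position, or None."""
        self._ensure_index()
        starts, genes = self._index.get(chrom, ([], []))
        i = bisect_right(starts, pos) - 1
        if i >= 0 and genes[i].start <= pos <= genes[i].end:
            return genes[i]
        return None

    def cds_sequence(self, gene: Gene) -> str:
        """Coding sequence of a gene, read 5'→3' on its own strand."""
        raw = self.chromosomes[gene.chrom][gene.start - 1 : gene.end]
        return revcomp(raw) if gene.strand == "-" else raw

    # -------------------------------------------------------------- invariants
    def validate(self) -> None:
        """Raise ValueError on the first violated genome invariant.

        Checks: gene within chromosome bounds, CDS length divisible by 3,
        start/stop codons on the gene's own strand, no overlapping genes.
        """
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")
            if g.length % 3:
                raise ValueError(f"gene {g.gene_id} CDS length not divisible by 3")
            cds = self.cds_sequence(g)
            if cds[:3] != START_CODON:
                raise ValueError(f"gene {g.gene_id} does not begin with ATG")
            if cds[-3:] not in STOP_CODONS:
                raise ValueError(f"gene {g.gene_id} does not end with a stop codon")
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in by_chrom.items():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"genes {a.gene_id} and {b.gene_id} overlap on {chrom}"
                    )

    # --------------------------------------------------------------------- I/O
    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in sorted(self.genes, key=lambda g: (self.chrom_names.index(g.chrom), g.start)):
                fh.write(
                    f"{g.chrom}\tcinpipe\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )


def read_genome(fasta_path: str | Path, gff3_path: str | Path | None = None) -> GenomeModel:
    """Load a GenomeModel from FASTA and (optionally) GFF3 gene features.

    Only features of type ``gene`` with an ``ID`` attribute are used;
    anything else in the GFF3 is ignored.
    """
    chromosomes = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    genes: list[Gene] = []
    if gff3_path is not None:
        import gffutils

        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        for feat in db.features_of_type("gene"):
            genes.append(
                Gene(
                    gene_id=feat.attributes["ID"][0],
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    return GenomeModel(chromosomes=chromosomes, genes=genes)
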