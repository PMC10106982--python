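"""End-to-end orchestration: simulate → karyotype → annotate → summarize.

A run either consumes existing files (FASTA + GFF3 genome, per-strain
bedGraph depth tracks and VCFs, a gene-category list) or simulates a
cohort first, then processes everything through the same file-based path
so the simulated route exercises the real readers.  Outputs are
per-strain karyotype tables and segment BEDs, annotated-variant tables, a
cohort summary, an enrichment result, and a machine-readable JSON report.
The whole run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeModel, read_genome
from .karyotype import (
    DepthTrack,
    KaryotypeParams,
    call_karyotype,
    detect_segments,
    disomic_set,
    flag_large_segmental,
    karyotype_table,
    reference_depth,
    segments_to_bed,
    telomere_window_depth,
)
from .simulate import (
    KaryotypeTruth,
    SimulationConfig,
    child_rng,
    generate_genome,
    random_karyotype_truth,
    simulate_depth,
    simulate_variants,
)
from .stats import GeneSet, StrainSummary, cin_enrichment, summarize_collection
from .variants import (
    FilterParams,
    annotate_variants,
    annotation_table,
    filter_variants,
    read_vcf,
    select_nonsynonymous,
    subtract_ancestor,
    write_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``simulate=True`` all inputs are generated under ``out_dir`` from
    the root seed; otherwise the path fields must point at existing files.
    """

    out_dir: str
    seed: int = 0
    simulate: bool = True
    n_strains: int = 10
    max_disomies: int = 3
    n_ancestral_variants: int = 20
    novel_per_class: dict[str, int] = field(
        default_factory=lambda: {"noncoding": 2, "silent": 1, "missense": 2, "nonsense": 1}
    )
    category_fraction_of_genes: float = 874 / 6002  # mirrors the CIN category share
    # file-mode inputs
    genome_fasta: str | None = None
    genome_gff: str | None = None
    depth_dir: str | None = None
    vcf_dir: str | None = None
    ancestor_vcf: str | None = None
    category_tsv: str | None = None
    universe_size: int | None = None
    # stage parameters
    karyotype: KaryotypeParams = field(default_factory=KaryotypeParams)
    filters: FilterParams = field(default_factory=FilterParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    genome_n_chrom: int = 16
    genome_length_range: tuple[int, int] = (150_000, 300_000)
    gene_density: float = 0.35

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("karyotype", KaryotypeParams), ("filters", FilterParams), ("sim", SimulationConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "genome_length_range" in raw:
            raw["genome_length_range"] = tuple(raw["genome_length_range"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


# ----------------------------------------------------------------- validation
def validate_inputs(
    genome: GenomeModel,
    tracks: dict[str, DepthTrack] | None = None,
    vcf_records: dict[str, list] | None = None,
) -> list[Diagnostic]:
    """Cross-consistency checks; returns diagnostics, mutates nothing.

    Checks genome invariants (gene bounds, CDS translatability), depth-
    track tiling against chromosome lengths, and VCF reference-base
    agreement with the FASTA.
    """
    out: list[Diagnostic] = []
    try:
        genome.validate()
    except ValueError as err:
        out.append(Diagnostic("error", f"genome: {err}"))
    for name, track in (tracks or {}).items():
        for chrom, L in track.chrom_lengths.items():
            if chrom not in genome.chromosomes:
                out.append(Diagnostic("error", f"{name}: unknown chromosome {chrom}"))
            elif genome.chrom_length(chrom) != L:
                out.append(
                    Diagnostic(
                        "error",
                        f"{name}: {chrom} length {L} != genome {genome.chrom_length(chrom)}",
                    )
                )
    for name, records in (vcf_records or {}).items():
        for rec in records:
            if rec.chrom not in genome.chromosomes:
                out.append(Diagnostic("error", f"{name}: unknown chromosome {rec.chrom}"))
            elif not 1 <= rec.pos <= genome.chrom_length(rec.chrom):
                out.append(Diagnostic("error", f"{name}: {rec.chrom}:{rec.pos} out of bounds"))
            elif genome.base_at(rec.chrom, rec.pos) != rec.ref:
                out.append(
                    Diagnostic(
                        "error",
                        f"{name}: ref mismatch at {rec.chrom}:{rec.pos} "
                        f"(VCF {rec.ref}, FASTA {genome.base_at(rec.chrom, rec.pos)})",
                    )
                )
    return out


# ------------------------------------------------------------------ simulate
def _simulate_inputs(cfg: RunConfig, out: Path) -> dict:
    """Generate genome, per-strain depth/VCF files and the category list."""
    sim_dir = out / "inputs"
    sim_dir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(
        n_chrom=cfg.genome_n_chrom,
        length_range=cfg.genome_length_range,
        gene_density=cfg.gene_density,
        seed=cfg.seed,
    )
    genome.to_fasta(sim_dir / "genome.fa")
    genome.to_gff3(sim_dir / "genes.gff3")
    sim = SimulationConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
    rng = child_rng(cfg.seed, "pipeline-truth")
    ancestor, _, _ = simulate_variants(genome, cfg.n_ancestral_variants, {}, sim, "ancestor")
    write_vcf(ancestor, sim_dir / "ancestor.vcf")
    truths: dict[str, KaryotypeTruth] = {}
    for i in range(cfg.n_strains):
        strain = f"strain{i + 1:03d}"
        truth = random_karyotype_truth(
            genome.chrom_lengths(), int(rng.integers(0, cfg.max_disomies + 1)), rng
        )
        truths[strain] = truth
        track = simulate_depth(genome, truth, sim, strain)
        track.to_bedgraph(sim_dir / f"{strain}.bedgraph")
        _, _, novel = simulate_variants(genome, 0, cfg.novel_per_class, sim, strain)
        write_vcf(ancestor + [t.record for t in novel], sim_dir / f"{strain}.vcf")
    gene_ids = [g.gene_id for g in genome.genes]
    k = max(1, int(round(cfg.category_fraction_of_genes * len(gene_ids))))
    cat_rng = child_rng(cfg.seed, "category")
    category = sorted(
        gene_ids[int(i)] for i in cat_rng.choice(len(gene_ids), size=k, replace=False)
    )
    pd.Series(category, name="gene_id").to_csv(
        sim_dir / "category.tsv", sep="\t", index=False
    )
    return {
        "genome_fasta": str(sim_dir / "genome.fa"),
        "genome_gff": str(sim_dir / "genes.gff3"),
        "depth_dir": str(sim_dir),
        "vcf_dir": str(sim_dir),
        "ancestor_vcf": str(sim_dir / "ancestor.vcf"),
        "category_tsv": str(sim_dir / "category.tsv"),
        "universe_size": len(gene_ids),
        "truth": {s: sorted(t.disomic_set) for s, t in truths.items()},
    }


# ----------------------------------------------------------------------- run
def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        paths = _simulate_inputs(cfg, out)
    else:
        required = ("genome_fasta", "genome_gff", "depth_dir", "vcf_dir", "ancestor_vcf", "category_tsv")
        missing = [k for k in required if getattr(cfg, k) is None]
        if missing:
            raise StageError("config", f"missing inputs: {', '.join(missing)}")
        paths = {k: getattr(cfg, k) for k in required}
        paths["universe_size"] = cfg.universe_size

    # ---- load & validate
    try:
        genome = read_genome(paths["genome_fasta"], paths["genome_gff"])
    except Exception as err:
        raise StageError("load-genome", str(err)) from err
    depth_files = sorted(Path(paths["depth_dir"]).glob("*.bedgraph"))
    vcf_files = {
        p.stem: p
        for p in sorted(Path(paths["vcf_dir"]).glob("*.vcf"))
        if p.name != Path(paths["ancestor_vcf"]).name
    }
    if not depth_files:
        raise StageError("load-depth", f"no .bedgraph files in {paths['depth_dir']}")
    tracks = {
        p.stem: DepthTrack.from_bedgraph(p, genome.chrom_lengths()) for p in depth_files
    }
    ancestor = read_vcf(paths["ancestor_vcf"])
    evolved = {s: read_vcf(p) for s, p in vcf_files.items()}
    diags = validate_inputs(genome, tracks, {**evolved, "ancestor": ancestor})
    errors = [d for d in diags if d.severity == "error"]
    if errors:
        raise StageError("validate", "; ".join(d.message for d in errors[:5]))

    # ---- karyotypes
    kdir = out / "karyotypes"
    kdir.mkdir(exist_ok=True)
    strains: list[StrainSummary] = []
    for strain, track in tracks.items():
        calls = call_karyotype(track, cfg.karyotype)
        karyotype_table(calls).to_csv(kdir / f"{strain}.karyotype.tsv", sep="\t", index=False)
        depths = [telomere_window_depth(track, c, cfg.karyotype) for c in track.chrom_names]
        ref = reference_depth(depths, mode=cfg.karyotype.reference_mode)
        seg_track = track.rebin(cfg.karyotype.segment_bin_size)
        segments = detect_segments(seg_track, ref, cfg.karyotype)
        segments_to_bed(segments, kdir / f"{strain}.segments.bed")
        strains.append(
            StrainSummary(
                strain_id=strain,
                disomic_chroms=disomic_set(calls),
                excluded=flag_large_segmental(segments, cfg.karyotype),
            )
        )

    # ---- variants
    vdir = out / "variants"
    vdir.mkdir(exist_ok=True)
    mutated_gene_hits: list[str] = []
    n_novel_total = 0
    ancestor_f = filter_variants(ancestor, cfg.filters)
    for strain, records in sorted(evolved.items()):
        kept = filter_variants(records, cfg.filters)
        novel = subtract_ancestor(kept, ancestor_f)
        annotated = annotate_variants(novel, genome)
        annotation_table(annotated).to_csv(
            vdir / f"{strain}.variants.tsv", sep="\t", index=False
        )
        n_novel_total += len(annotated)
        mutated_gene_hits.extend(a.gene_id for a in select_nonsynonymous(annotated))

    # ---- cohort statistics
    category = set(
        pd.read_csv(paths["category_tsv"], sep="\t")["gene_id"].astype(str)
    )
    universe = paths.get("universe_size") or len(genome.genes)
    geneset = GeneSet(genes=category, universe_size=universe)
    summary = summarize_collection(strains, chroms=list(genome.chrom_names))
    enrichment = cin_enrichment(mutated_gene_hits, geneset)

    report = {
        "cinpipe_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "karyotype": asdict(cfg.karyotype),
            "filters": asdict(cfg.filters),
            "simulation": asdict(cfg.sim) if cfg.simulate else None,
        },
        "n_strains": len(strains),
        "strains": {
            s.strain_id: {
                "disomic": sorted(s.disomic_chroms),
                "excluded": s.excluded,
            }
            for s in strains
        },
        "cohort": {
            "mean_disomies_per_strain": summary.mean_disomies,
            "n_excluded": summary.n_excluded,
            "chrom_frequency": summary.chrom_frequency,
        },
        "variants": {"n_novel_annotated": n_novel_total, "n_nonsynonymous_hits": len(mutated_gene_hits)},
        "enrichment": {
            "k": enrichment.k,
            "n": enrichment.n,
            "K": enrichment.K,
            "N": enrichment.N,
            "fraction_pct": enrichment.fraction_pct,
            "p_value": enrichment.p_value,
        },
        "warnings": [d.message for d in diags if d.severity == "warning"],
    }
    if cfg.simulate:
        report["truth"] = paths["truth"]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
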