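"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a haploid
16-chromosome genome with single-exon protein-coding genes on both
strands, binned depth tracks with Poisson (or negative-binomial) noise and
planted disomies/segmental amplifications, ancestor/evolved variant sets
with known effect classes, and synthetic fluorescence and plate images.

All randomness flows from one root seed: each generator derives an
independent child stream from ``(seed, label)`` so that adding a new
generator never perturbs existing outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome import Gene, GenomeModel, STOP_CODONS, revcomp
from .karyotype import DepthTrack
from .variants import VariantRecord, classify_effect

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]


def child_rng(seed: int, *labels: str | int) -> np.random.Generator:
    """Deterministic child stream derived from a root seed and labels."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        entropy.append(zlib.crc32(str(lab).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# -------------------------------------------------------------- configuration
@dataclass
class SimulationConfig:
    """Knobs of the cohort simulation.

    coverage : mean reads per full-size bin on a single-copy region (λ).
    bin_size : depth-track bin width in bp.
    noise : "poisson" or "negative-binomial" (the latter with
        ``dispersion`` such that variance = m + m**2/dispersion).
    qual_range : uniform range for simulated variant quality scores;
        the default straddles the quality filter so some records are
        deliberately sub-threshold.
    depth_mean/depth_sd : normal distribution of simulated per-variant
        read depth (clipped at 1); the default puts a tail above the
        depth cutoff.
    """

    seed: int = 0
    coverage: float = 100.0
    bin_size: int = 1_000
    noise: str = "poisson"
    dispersion: float = 20.0
    n_strains: int = 10
    qual_range: tuple[float, float] = (50.0, 255.0)
    depth_mean: float = 180.0
    depth_sd: float = 80.0

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.noise not in ("poisson", "negative-binomial"):
            raise ValueError("noise must be 'poisson' or 'negative-binomial'")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class KaryotypeTruth:
    """Planted copy-number state of one simulated strain.

    Baseline ploidy is haploid; ``chrom_copies`` lists per-chromosome
    integer copies (1 or 2), ``segments`` holds sub-chromosomal events as
    (chrom, start, end, copy_number) with 0-based half-open coordinates.
    """

    chrom_copies: dict[str, int]
    segments: list[tuple[str, int, int, int]] = field(default_factory=list)

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for chrom, cn in self.chrom_copies.items():
            if cn not in (1, 2):
                raise ValueError(f"{chrom}: copy number must be 1 or 2, got {cn}")
        for chrom, start, end, cn in self.segments:
            if not 0 <= start < end <= chrom_lengths[chrom]:
                raise ValueError(f"segment out of bounds: {chrom}:{start}-{end}")
            if cn < 1:
                raise ValueError("segment copy number must be >= 1")

    @property
    def disomic_set(self) -> set[str]:
        return {c for c, cn in self.chrom_copies.items() if cn == 2}


# ------------------------------------------------------------ genome
def generate_genome(
    n_chrom: int = 16,
    length_range: tuple[int, int] = (200_000, 400_000),
    gene_density: float = 0.35,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 1_500),
) -> GenomeModel:
    """Random haploid genome with non-overlapping single-exon CDS genes.

    ``gene_density`` is genes per kb.  Genes are placed by walking each
    chromosome with exponential intergenic gaps tuned to the requested
    density; each CDS is ATG + non-stop codons + stop, on a random strand
    (reverse-complemented into the chromosome for '-' genes).

    Raises ValueError when the requested density cannot accommodate the
    gene length range.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    lo_len, hi_len = length_range
    if lo_len < 1 or hi_len < lo_len:
        raise ValueError("invalid length_range")
    rng = child_rng(seed, "genome")
    mean_gene = (gene_length_range[0] + gene_length_range[1]) / 2
    if gene_density > 0:
        spacing = 1_000.0 / gene_density  # mean bp per gene
        mean_gap = spacing - mean_gene
        if mean_gap < 30:
            raise ValueError(
                f"gene density {gene_density}/kb cannot fit genes of mean "
                f"length {mean_gene:.0f} bp"
            )
    chromosomes: dict[str, str] = {}
    genes: list[Gene] = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1:02d}"
        L = int(rng.integers(lo_len, hi_len + 1))
        seq = rng.choice(_BASES, size=L)
        if gene_density > 0:
            pos = int(rng.exponential(mean_gap)) + 1  # leave >= 1 bp margin
            gi = 0
            while True:
                n_codons = int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3 + 1))
                glen = n_codons * 3
                if pos + glen > L:
                    break
                gi += 1
                strand = "+" if rng.random() < 0.5 else "-"
                body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
                stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
                cds = "ATG" + "".join(body) + stop
                placed = cds if strand == "+" else revcomp(cds)
                seq[pos : pos + glen] = list(placed)
                genes.append(
                    Gene(
                        gene_id=f"{name}g{gi:04d}",
                        chrom=name,
                        start=pos + 1,
                        end=pos + glen,
                        strand=strand,
                    )
                )
                pos += glen + int(rng.exponential(mean_gap)) + 2
        chromosomes[name] = "".join(seq)
    return GenomeModel(chromosomes=chromosomes, genes=genes)


# ------------------------------------------------------------ depth
def simulate_depth(
    genome: GenomeModel | dict[str, int],
    truth: KaryotypeTruth,
    cfg: SimulationConfig,
    strain_label: str | int = 0,
) -> DepthTrack:
    """Binned read counts with per-bin mean λ × local copy number.

    ``genome`` may be a GenomeModel or a plain chromosome-length mapping
    (sequence content does not influence coverage).  Partial trailing bins
    have proportionally reduced expected counts.
    """
    chrom_lengths = (
        genome.chrom_lengths() if isinstance(genome, GenomeModel) else dict(genome)
    )
    truth.validate(chrom_lengths)
    rng = child_rng(cfg.seed, "depth", strain_label)
    counts: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        edges = np.append(np.arange(0, L, cfg.bin_size), L)
        starts, ends = edges[:-1], edges[1:]
        base_cn = float(truth.chrom_copies.get(chrom, 1))
        # expected copies integrated over each bin (segments may partially overlap)
        copy_bp = base_cn * (ends - starts).astype(float)
        for seg_chrom, s, e, cn in truth.segments:
            if seg_chrom != chrom:
                continue
            overlap = np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None)
            copy_bp += (cn - base_cn) * overlap
        mean = cfg.coverage * copy_bp / cfg.bin_size
        if cfg.noise == "poisson":
            counts[chrom] = rng.poisson(mean).astype(float)
        else:
            r = cfg.dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(mean > 0, r / (r + mean), 1.0)
            counts[chrom] = rng.negative_binomial(r, p).astype(float) * (mean > 0)
    return DepthTrack(bin_size=cfg.bin_size, chrom_lengths=chrom_lengths, counts=counts)


def random_karyotype_truth(
    chrom_lengths: dict[str, int],
    n_disomies: int,
    rng: np.random.Generator,
) -> KaryotypeTruth:
    """Uniformly pick ``n_disomies`` chromosomes to carry two copies."""
    names = list(chrom_lengths)
    if n_disomies > len(names):
        raise ValueError("more disomies requested than chromosomes")
    disomic = rng.choice(len(names), size=n_disomies, replace=False)
    copies = {name: 1 for name in names}
    for i in disomic:
        copies[names[int(i)]] = 2
    return KaryotypeTruth(chrom_copies=copies)


# ------------------------------------------------------------ variants
@dataclass(frozen=True)
class VariantTruth:
    record: VariantRecord
    effect: str


def _draw_attrs(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[float, int]:
    qual = float(rng.uniform(*cfg.qual_range))
    depth = max(1, int(round(rng.normal(cfg.depth_mean, cfg.depth_sd))))
    return qual, depth


def _random_variant_of_class(
    genome: GenomeModel,
    effect: str,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    used: set[tuple[str, int]],
    max_tries: int = 20_000,
) -> VariantRecord:
    """Rejection-sample a substitution whose classified effect matches."""
    chroms = genome.chrom_names
    coding = [g for g in genome.genes]
    if effect != "noncoding" and not coding:
        raise ValueError(f"no genes available to place a {effect} variant")
    for _ in range(max_tries):
        if effect == "noncoding":
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, genome.chrom_length(chrom) + 1))
            if genome.gene_at(chrom, pos) is not None:
                continue
        else:
            g = coding[int(rng.integers(len(coding)))]
            chrom = g.chrom
            pos = int(rng.integers(g.start, g.end + 1))
        if (chrom, pos) in used:
            continue
        ref = genome.base_at(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        qual, depth = _draw_attrs(rng, cfg)
        rec = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, depth=depth)
        if classify_effect(rec, genome).effect == effect:
            used.add((chrom, pos))
            return rec
    raise ValueError(
        f"could not place a {effect!r} variant after {max_tries} draws "
        "(no eligible site in this genome?)"
    )


def simulate_variants(
    genome: GenomeModel,
    n_ancestral: int,
    n_novel_by_class: dict[str, int],
    cfg: SimulationConfig,
    strain_label: str | int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantTruth]]:
    """Ancestor and evolved variant sets with ground-truth effect labels.

    The evolved set is the ancestor set plus exactly the requested novel
    records per effect class; the returned truth list covers the novel
    records only.  Quality and depth attributes are drawn from ``cfg``
    and intentionally straddle the default filter thresholds.
    """
    unknown = set(n_novel_by_class) - {"noncoding", "silent", "missense", "nonsense"}
    if unknown:
        raise ValueError(f"unknown effect classes: {sorted(unknown)}")
    rng = child_rng(cfg.seed, "variants", strain_label)
    used: set[tuple[str, int]] = set()
    ancestor: list[VariantRecord] = []
    while len(ancestor) < n_ancestral:
        # ancestral background mutations: any effect class
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        pos = int(rng.integers(1, genome.chrom_length(chrom) + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome.base_at(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        qual, depth = _draw_attrs(rng, cfg)
        ancestor.append(VariantRecord(chrom, pos, ref, alt, qual, depth))
    truth: list[VariantTruth] = []
    for effect in ("noncoding", "silent", "missense", "nonsense"):
        for _ in range(n_novel_by_class.get(effect, 0)):
            rec = _random_variant_of_class(genome, effect, rng, cfg, used)
            truth.append(VariantTruth(record=rec, effect=effect))
    evolved = ancestor + [t.record for t in truth]
    return ancestor, evolved, truth


# ------------------------------------------------------------ cohort genes
def simulate_mutation_cohort(
    n_strains: int,
    mutations_per_strain: float,
    universe: int,
    category_size: int,
    enrichment_factor: float,
    seed: int,
) -> tuple[list[str], set[str]]:
    """Gene-level mutation hits for a cohort, with category enrichment.

    Each strain acquires Poisson(``mutations_per_strain``) gene hits; a
    hit falls inside the category with probability
    ``f*K / (f*K + (N-K))`` where f is the enrichment factor (f = 1 is the
    null).  Returns the flat hit list (gene ids, repeats possible across
    strains) and the category gene-id set.
    """
    if not 0 < category_size <= universe:
        raise ValueError("need 0 < category_size <= universe")
    rng = child_rng(seed, "cohort")
    gene_ids = [f"G{i:05d}" for i in range(universe)]
    category = set(gene_ids[:category_size])
    p_cat = (enrichment_factor * category_size) / (
        enrichment_factor * category_size + (universe - category_size)
    )
    hits: list[str] = []
    for _ in range(n_strains):
        for _ in range(rng.poisson(mutations_per_strain)):
            if rng.random() < p_cat:
                hits.append(gene_ids[int(rng.integers(category_size))])
            else:
                hits.append(gene_ids[int(rng.integers(category_size, universe))])
    return hits, category


# ------------------------------------------------------------ images
@dataclass
class SpindleImageTruth:
    """Per-spot ground truth: (x, y, amplitude, sigma, integrated intensity)."""

    spots: list[tuple[float, float, float, float, float]]
    background: float


def synthesize_spindle_image(
    spot_params: list[tuple[float, float, float, float]],
    background: float = 100.0,
    noise_sd: float = 0.0,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> tuple[np.ndarray, SpindleImageTruth]:
    """Sum of isotropic 2-D Gaussian spots on a flat background.

    ``spot_params`` entries are (x, y, amplitude, sigma) in pixel units
    (x = column, y = row).  The true integrated intensity of each spot is
    2π·A·σ².  Additive Gaussian noise; intensities clipped at zero.
    """
    h, w = size
    for x, y, _, _ in spot_params:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"spot ({x}, {y}) outside {w}x{h} image")
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), float(background))
    truth = []
    for x, y, amp, sigma in spot_params:
        img += amp * np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)))
        truth.append((x, y, amp, sigma, 2.0 * np.pi * amp * sigma**2))
    if noise_sd > 0:
        img += child_rng(seed, "spindle").normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, None), SpindleImageTruth(spots=truth, background=background)


@dataclass
class PlateImageTruth:
    n_disks: int
    covered_fraction: float  # of the whole image area
    centers: list[tuple[float, float]]
    radii: list[float]


def synthesize_plate_image(
    disk_centers: list[tuple[float, float]],
    radii: list[float] | float,
    foreground: float = 200.0,
    background: float = 50.0,
    size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, PlateImageTruth]:
    """Uniform disks (colonies) on a flat background, pixel-center sampled."""
    h, w = size
    if np.isscalar(radii):
        radii = [float(radii)] * len(disk_centers)
    if len(radii) != len(disk_centers):
        raise ValueError("radii and disk_centers length mismatch")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for (x, y), r in zip(disk_centers, radii):
        mask |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
    img = np.where(mask, float(foreground), float(background))
    if noise_sd > 0:
        img = img + child_rng(seed, "plate").normal(0.0, noise_sd, size=img.shape)
    truth = PlateImageTruth(
        n_disks=len(disk_centers),
        covered_fraction=float(mask.mean()),
        centers=[(float(x), float(y)) for x, y in disk_centers],
        radii=[float(r) for r in radii],
    )
    return np.clip(img, 0.0, None), truth


def random_plate(
    n_disks: int,
    rng: np.random.Generator,
    size: tuple[int, int] = (256, 256),
    radius_range: tuple[float, float] = (5.0, 10.0),
    margin: float = 12.0,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, PlateImageTruth]:
    """Non-overlapping random disks fully inside the frame."""
    h, w = size
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n_disks:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"could not place {n_disks} non-overlapping disks")
        r = rng.uniform(*radius_range)
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all(
            (x - cx) ** 2 + (y - cy) ** 2 > (r + cr + 2.0) ** 2
            for (cx, cy), cr in zip(centers, radii)
        ):
            centers.append((x, y))
            radii.append(r)
    return synthesize_plate_image(centers, radii, size=size)
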