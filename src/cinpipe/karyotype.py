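"""Whole-chromosome copy-number calling and segmental amplification detection.

The caller reproduces the read-depth normalization used to karyotype
haploid evolved yeast strains from whole-genome sequencing coverage:

1. For each chromosome, mean per-bp depth is measured over a fixed-length
   window at the chromosome end(s) ("telomere window", default 15 kb per
   end) so that chromosomes of very different lengths contribute equally.
2. The euploid reference depth is the mean of the chromosomes whose
   per-chromosome value falls in the second-lowest quartile of the ranked
   values — disomic chromosomes land in the upper quartiles and cannot
   inflate the baseline.
3. Normalized copy number = window depth / reference depth; a chromosome
   is called disomic when the value is strictly greater than the disomy
   threshold (default 1.5).

Segmental amplifications are detected on a coarser binning (default 4 kb)
as maximal runs of consecutive bins whose depth ratio exceeds a threshold;
strains carrying large sub-chromosomal amplifications can then be flagged
for exclusion from cohort aneuploidy statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


# ----------------------------------------------------------------- containers
@dataclass
class DepthTrack:
    """Binned read counts tiling each chromosome.

    Bins are 0-based half-open ``[i*bin_size, min((i+1)*bin_size, L))``;
    the last bin of a chromosome may be short.  ``counts`` maps chromosome
    name to an integer-or-float array of reads per bin.
    """

    bin_size: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            expected = math.ceil(length / self.bin_size)
            arr = np.asarray(self.counts[chrom], dtype=float)
            if arr.ndim != 1 or len(arr) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins for length {length} "
                    f"at bin size {self.bin_size}, got {len(arr)}"
                )
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative bin counts")
            self.counts[chrom] = arr

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_reads(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def bin_edges(self, chrom: str) -> np.ndarray:
        """Bin boundary positions 0, b, 2b, ..., L for a chromosome."""
        L = self.chrom_lengths[chrom]
        edges = np.arange(0, L, self.bin_size)
        return np.append(edges, L)

    def bin_lengths(self, chrom: str) -> np.ndarray:
        return np.diff(self.bin_edges(chrom))

    def scaled(self, factor: float) -> "DepthTrack":
        """Return a copy with every bin count multiplied by ``factor``."""
        return DepthTrack(
            bin_size=self.bin_size,
            chrom_lengths=dict(self.chrom_lengths),
            counts={c: arr * factor for c, arr in self.counts.items()},
        )

    def rebin(self, new_bin_size: int) -> "DepthTrack":
        """Aggregate counts into larger bins (new size a multiple of old)."""
        if new_bin_size % self.bin_size:
            raise ValueError("new bin size must be a multiple of the current one")
        k = new_bin_size // self.bin_size
        new_counts = {}
        for chrom, arr in self.counts.items():
            n_new = math.ceil(len(arr) / k)
            padded = np.zeros(n_new * k)
            padded[: len(arr)] = arr
            new_counts[chrom] = padded.reshape(n_new, k).sum(axis=1)
        return DepthTrack(
            bin_size=new_bin_size,
            chrom_lengths=dict(self.chrom_lengths),
            counts=new_counts,
        )

    # ------------------------------------------------------------------- I/O
    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_names:
                edges = self.bin_edges(chrom)
                for start, end, count in zip(edges[:-1], edges[1:], self.counts[chrom]):
                    fh.write(f"{chrom}\t{start}\t{end}\t{count:g}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, chrom_lengths: dict[str, int] | None = None
    ) -> "DepthTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "count"],
            dtype={"chrom": str},
        )
        if df.empty:
            raise ValueError(f"empty bedGraph: {path}")
        bin_size = int((df["end"] - df["start"]).max())
        if chrom_lengths is None:
            chrom_lengths = df.groupby("chrom", sort=False)["end"].max().astype(int).to_dict()
        counts = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            expected_starts = np.arange(0, chrom_lengths[chrom], bin_size)
            if not np.array_equal(sub["start"].to_numpy(), expected_starts):
                raise ValueError(f"{chrom}: bins do not tile the chromosome")
            counts[chrom] = sub["count"].to_numpy(dtype=float)
        return cls(bin_size=bin_size, chrom_lengths=chrom_lengths, counts=counts)


@dataclass(frozen=True)
class ChromCopyCall:
    chrom: str
    telomere_depth: float  # reads per bp in the telomere window(s)
    copy_number: float  # normalized, euploid ~ 1
    disomic: bool


@dataclass(frozen=True)
class SegmentCall:
    """A run of consecutive elevated-depth bins.

    Coordinates are 0-based half-open multiples of the segment bin size;
    ``end`` is clipped to the chromosome length when the run includes the
    trailing partial bin, so ``n_bins * bin_size == end - start`` holds for
    interior segments only.
    """

    chrom: str
    start: int
    end: int
    mean_ratio: float
    n_bins: int
    spans_chromosome: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class KaryotypeParams:
    """Constants of the depth-normalization scheme.

    telomere_window : bp of chromosome end used for depth sampling
        (both ends by default; per-end window).
    disomy_threshold : normalized copy number strictly above which a
        chromosome is called disomic.
    segment_bin_size : bp binning at which segmental events are detected.
    segment_ratio_threshold : depth ratio above which a 4 kb bin counts as
        amplified.
    min_segment_bins : minimum consecutive amplified bins per segment.
    large_segment_length : bp above which a sub-chromosomal amplification
        flags the strain for exclusion from cohort statistics.
    """

    telomere_window: int = 15_000
    disomy_threshold: float = 1.5
    segment_bin_size: int = 4_000
    segment_ratio_threshold: float = 1.5
    min_segment_bins: int = 5
    large_segment_length: int = 100_000
    both_ends: bool = True
    reference_mode: str = "mean"  # or "median" within the quartile slice

    def __post_init__(self) -> None:
        for name in (
            "telomere_window",
            "disomy_threshold",
            "segment_bin_size",
            "segment_ratio_threshold",
            "min_segment_bins",
            "large_segment_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reference_mode not in ("mean", "median"):
            raise ValueError("reference_mode must be 'mean' or 'median'")


# ----------------------------------------------------------------- operations
def _window_depth(track: DepthTrack, chrom: str, lo: int, hi: int) -> tuple[float, int]:
    """(reads overlapping [lo,hi), bp) — bins contribute pro rata."""
    edges = track.bin_edges(chrom)
    starts, ends = edges[:-1], edges[1:]
    overlap = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
    frac = overlap / (ends - starts)
    return float((track.counts[chrom] * frac).sum()), int(overlap.sum())


def telomere_window_depth(
    track: DepthTrack, chrom: str, params: KaryotypeParams | None = None
) -> float:
    """Mean per-bp depth over the telomere-proximal window(s) of a chromosome.

    Uses the first and last ``telomere_window`` bp (both-ends mode) or the
    last only.  If the windows would cover the whole chromosome (two
    windows meeting or overlapping), falls back to the whole-chromosome
    mean per-bp depth.
    """
    params = params or KaryotypeParams()
    if chrom not in track.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    L = track.chrom_lengths[chrom]
    w = params.telomere_window
    n_windows = 2 if params.both_ends else 1
    if n_windows * w >= L:
        reads, bp = _window_depth(track, chrom, 0, L)
        return reads / bp
    if params.both_ends:
        r1, b1 = _window_depth(track, chrom, 0, w)
        r2, b2 = _window_depth(track, chrom, L - w, L)
        return (r1 + r2) / (b1 + b2)
    reads, bp = _window_depth(track, chrom, L - w, L)
    return reads / bp


def reference_depth(per_chrom_values, mode: str = "mean") -> float:
    """Euploid baseline: mean of the second-lowest quartile of values.

    Values are ranked ascending; ranks ``ceil(n/4)+1 .. ceil(n/2)``
    (1-based) form the slice — for 16 chromosomes, ranks 5-8.  Robust to
    disomic chromosomes, which occupy the top quartiles.
    """
    values = np.asarray(list(per_chrom_values), dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError(f"need at least 4 chromosomes, got {n}")
    if not values.any():
        raise ValueError("all per-chromosome depths are zero (no coverage)")
    lo = math.ceil(n / 4)
    hi = math.ceil(n / 2)
    chunk = np.sort(values)[lo:hi]
    return float(np.median(chunk) if mode == "median" else chunk.mean())


def call_karyotype(
    track: DepthTrack, params: KaryotypeParams | None = None
) -> list[ChromCopyCall]:
    """Per-chromosome normalized copy number and disomy calls.

    Copy number = telomere-window depth / second-quartile reference; the
    disomy flag uses a strict inequality against the threshold, so a value
    of exactly 1.5 stays euploid.
    """
    params = params or KaryotypeParams()
    depths = {c: telomere_window_depth(track, c, params) for c in track.chrom_names}
    ref = reference_depth(depths.values(), mode=params.reference_mode)
    return [
        ChromCopyCall(
            chrom=c,
            telomere_depth=d,
            copy_number=d / ref,
            disomic=d / ref > params.disomy_threshold,
        )
        for c, d in depths.items()
    ]


def disomic_set(calls: list[ChromCopyCall]) -> set[str]:
    return {c.chrom for c in calls if c.disomic}


def detect_segments(
    track: DepthTrack,
    reference_per_bp: float,
    params: KaryotypeParams | None = None,
) -> list[SegmentCall]:
    """Maximal runs of consecutive amplified bins on the segment binning.

    ``track`` must already be binned at ``params.segment_bin_size`` (see
    :meth:`DepthTrack.rebin`); ``reference_per_bp`` is the euploid per-bp
    depth (e.g. the reference computed by :func:`call_karyotype`).  A bin
    is amplified when its per-bp depth ratio strictly exceeds the segment
    ratio threshold; runs shorter than ``min_segment_bins`` are dropped.
    Whole-chromosome disomies appear as chromosome-spanning segments.
    """
    params = params or KaryotypeParams()
    if track.bin_size != params.segment_bin_size:
        raise ValueError(
            f"track bin size {track.bin_size} != segment bin size "
            f"{params.segment_bin_size}; rebin first"
        )
    if reference_per_bp <= 0:
        raise ValueError("reference depth must be positive")
    out: list[SegmentCall] = []
    for chrom in track.chrom_names:
        lengths = track.bin_lengths(chrom)
        ratio = track.counts[chrom] / lengths / reference_per_bp
        above = ratio > params.segment_ratio_threshold
        n = len(above)
        i = 0
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= params.min_segment_bins:
                start = i * track.bin_size
                end = min(j * track.bin_size, track.chrom_lengths[chrom])
                out.append(
                    SegmentCall(
                        chrom=chrom,
                        start=start,
                        end=end,
                        mean_ratio=float(ratio[i:j].mean()),
                        n_bins=j - i,
                        spans_chromosome=(i == 0 and j == n),
                    )
                )
            i = j
    out.sort(key=lambda s: (list(track.chrom_names).index(s.chrom), s.start))
    return out


def flag_large_segmental(
    segments: list[SegmentCall], params: KaryotypeParams | None = None
) -> bool:
    """True iff any sub-chromosomal segment reaches the exclusion length.

    Chromosome-spanning segments are whole-chromosome disomies, not
    segmental events, and never trigger the flag.
    """
    params = params or KaryotypeParams()
    return any(
        not s.spans_chromosome and s.length >= params.large_segment_length
        for s in segments
    )


# ------------------------------------------------------------------ reporting
def karyotype_table(calls: list[ChromCopyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "telomere_depth": [c.telomere_depth for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "disomic": [c.disomic for c in calls],
        }
    )


def segments_to_bed(segments: list[SegmentCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            name = "chromosome_span" if s.spans_chromosome else "segment"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{s.mean_ratio:.3f}\n")
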