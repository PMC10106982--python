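"""Cohort-level statistics for adapted strain collections.

Covers the gene-set enrichment of mutated genes against a chromosomal-
instability (CIN) category (exact hypergeometric upper tail), aneuploidy
summaries across a strain collection (mean disomies per strain, per-
chromosome aneuploidy frequency), minichromosome transmission fidelity,
and the unpaired two-sample t-test used for group comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A gene category within a finite annotated universe.

    ``universe_size`` is the number of annotated genes (N); ``genes`` is
    the category (size K <= N).
    """

    genes: set[str]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        if len(self.genes) > self.universe_size:
            raise ValueError("category larger than universe")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    k: int  # category hits among mutated genes
    n: int  # mutated genes counted
    K: int  # category size
    N: int  # universe size
    fraction_pct: float  # 100*k/n
    p_value: float  # hypergeometric upper tail P(X >= k)


def category_fraction(K: int, N: int) -> float:
    """Percentage of the gene universe occupied by a category (100·K/N)."""
    if N <= 0:
        raise ValueError("universe size must be positive")
    if not 0 <= K <= N:
        raise ValueError("need 0 <= K <= N")
    return 100.0 * K / N


def format_percent(value: float, decimals: int = 1) -> str:
    """Display formatting for percentages: truncate to the shown precision.

    Reported category percentages follow a truncating convention
    (874/6002 = 14.56% displays as 14.5%), so excess precision is cut,
    not rounded.  The underlying float is never altered.
    """
    scale = 10**decimals
    truncated = math.trunc(value * scale) / scale
    return f"{truncated:.{decimals}f}"


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def cin_enrichment(
    mutated_genes: list[str],
    geneset: GeneSet,
    mode: str = "per-hit",
) -> EnrichmentResult:
    """Exact enrichment of mutated genes in a category.

    ``mutated_genes`` is the list of gene hits across the strain
    collection.  In the default ``"per-hit"`` mode each listed hit counts
    (a gene mutated independently in two strains contributes twice,
    matching mutation-level tallies); ``"per-gene"`` deduplicates to
    unique genes first.  Genes outside the universe naming scheme cannot
    be detected here, but an oversized count is rejected.
    """
    if mode not in ("per-hit", "per-gene"):
        raise ValueError("mode must be 'per-hit' or 'per-gene'")
    hits = list(mutated_genes) if mode == "per-hit" else sorted(set(mutated_genes))
    k = sum(1 for g in hits if g in geneset.genes)
    n = len(hits)
    if n > geneset.universe_size:
        raise ValueError("more mutated genes than the universe holds")
    if n == 0:
        p = 1.0
    else:
        p = hypergeom_upper_tail(k, geneset.universe_size, geneset.size, n)
    return EnrichmentResult(
        k=k,
        n=n,
        K=geneset.size,
        N=geneset.universe_size,
        fraction_pct=(100.0 * k / n) if n else 0.0,
        p_value=p,
    )


# --------------------------------------------------------------- aneuploidy
@dataclass
class StrainSummary:
    strain_id: str
    disomic_chroms: set[str] = field(default_factory=set)
    excluded: bool = False  # large segmental amplification


@dataclass
class CollectionSummary:
    n_strains: int  # non-excluded strains counted
    n_excluded: int
    mean_disomies: float
    chrom_frequency: dict[str, float]  # fraction of counted strains disomic


def summarize_collection(
    strains: list[StrainSummary], chroms: list[str] | None = None
) -> CollectionSummary:
    """Mean disomies per strain and per-chromosome aneuploidy frequency.

    Strains flagged as carrying large segmental amplifications are
    excluded from both statistics.  ``chroms`` fixes the chromosome order
    of the frequency table (defaults to the union seen, sorted).
    """
    kept = [s for s in strains if not s.excluded]
    if not kept:
        raise ValueError("all strains excluded; nothing to summarize")
    if chroms is None:
        chroms = sorted({c for s in kept for c in s.disomic_chroms})
    mean = sum(len(s.disomic_chroms) for s in kept) / len(kept)
    freq = {
        c: sum(1 for s in kept if c in s.disomic_chroms) / len(kept) for c in chroms
    }
    return CollectionSummary(
        n_strains=len(kept),
        n_excluded=len(strains) - len(kept),
        mean_disomies=mean,
        chrom_frequency=freq,
    )


# ----------------------------------------------------------------- fidelity
def transmission_fidelity(colonies_restrictive: int, colonies_permissive: int) -> float:
    """Minichromosome retention: selective / nonselective colony counts.

    Values above 1 are possible through plating noise and are reported
    unclamped (a warning is logged).
    """
    if colonies_permissive <= 0:
        raise ValueError("permissive colony count must be positive")
    if colonies_restrictive < 0:
        raise ValueError("colony counts must be non-negative")
    ratio = colonies_restrictive / colonies_permissive
    if ratio > 1:
        log.warning("transmission fidelity %.3f > 1 (plating noise)", ratio)
    return ratio


# ------------------------------------------------------------------ t-test
def unpaired_t(
    group_a, group_b, mode: str = "student"
) -> tuple[float, float, float]:
    """Two-sample unpaired t-test: (t, df, two-sided p).

    ``mode="student"`` pools the variance (classic unpaired t-test, the
    default of common graphing software); ``"welch"`` drops the equal-
    variance assumption.  When both groups are constant and equal, the
    statistic is defined as t = 0, p = 1 by convention.
    """
    if mode not in ("student", "welch"):
        raise ValueError("mode must be 'student' or 'welch'")
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=(mode == "student"))
    df = float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    if t != t:  # zero variance in both groups
        if abs(sum(a) / len(a) - sum(b) / len(b)) < 1e-300:
            return 0.0, df if df == df else float(len(a) + len(b) - 2), 1.0
        raise ZeroDivisionError("zero variance with unequal means")
    return t, df, p


def benjamini_hochberg(p_values) -> list[float]:
    """BH-adjusted q-values for a batch of tests (FDR control helper)."""
    from statsmodels.stats.multitest import multipletests

    pv = list(p_values)
    if not pv:
        return []
    _, q, _, _ = multipletests(pv, method="fdr_bh")
    return [float(x) for x in q]
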