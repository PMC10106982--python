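"""Cohort statistics: CIN-gene enrichment, aneuploidy burden, t-test.

Uses the yeast-scale universe (6,002 annotated genes, 874 CIN-related)
and a simulated 50-strain cohort whose CIN-category genes mutate at three
times the background rate.
"""

from cinpipe.simulate import simulate_mutation_cohort
from cinpipe.stats import (
    GeneSet,
    StrainSummary,
    category_fraction,
    cin_enrichment,
    format_percent,
    summarize_collection,
    transmission_fidelity,
    unpaired_t,
)

frac = category_fraction(874, 6002)
print(f"CIN category: 874 of 6,002 genes = {format_percent(frac)}% of the universe")

hits, category = simulate_mutation_cohort(
    n_strains=50, mutations_per_strain=1.4, universe=6002,
    category_size=874, enrichment_factor=3.0, seed=0,
)
res = cin_enrichment(hits, GeneSet(genes=category, universe_size=6002))
print(f"enrichment: {res.k}/{res.n} mutated genes in category "
      f"({format_percent(res.fraction_pct)}%), hypergeometric p = {res.p_value:.3g}")

strains = [
    StrainSummary("ad1", {"chr03", "chr11"}),
    StrainSummary("ad2", {"chr03"}),
    StrainSummary("ad3", {"chr03", "chr08", "chr11"}),
    StrainSummary("ad4", set()),
    StrainSummary("ad5", {"chr02"}, excluded=True),  # large segmental amplification
]
summary = summarize_collection(strains)
print(f"mean disomies/strain: {summary.mean_disomies:.2f} "
      f"({summary.n_strains} strains, {summary.n_excluded} excluded)")
print(f"chr03 aneuploidy frequency: {summary.chrom_frequency['chr03']:.2f}")

print(f"minichromosome transmission fidelity 50/100 colonies: "
      f"{transmission_fidelity(50, 100):.2f}")

t, df, p = unpaired_t([0.52, 0.48, 0.61, 0.55], [0.31, 0.29, 0.38, 0.35])
print(f"unpaired t-test: t = {t:.2f}, df = {df:.0f}, p = {p:.4f}")
# A p below 0.05 in the enrichment test says the mutated-gene list hits
# the CIN category more often than random sampling of the universe would.
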