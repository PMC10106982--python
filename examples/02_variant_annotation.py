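"""Identify and classify mutations gained by an evolved strain.

Simulates an ancestor variant set plus novel mutations of each effect
class, then runs the evolved-vs-ancestor workflow: quality/depth
filtering (qual > 95, depth <= 300), ancestor subtraction, and
codon-level effect classification.
"""

from cinpipe.simulate import SimulationConfig, generate_genome, simulate_variants
from cinpipe.variants import (
    FilterParams,
    annotate_variants,
    annotation_table,
    filter_variants,
    select_nonsynonymous,
    subtract_ancestor,
)

genome = generate_genome(n_chrom=4, length_range=(80_000, 120_000), seed=1)
cfg = SimulationConfig(seed=1)
requested = {"missense": 3, "silent": 2, "nonsense": 1, "noncoding": 2}
ancestor, evolved, truth = simulate_variants(genome, 15, requested, cfg)

params = FilterParams()  # qual > 95, depth <= 300
kept = filter_variants(evolved, params)
novel = subtract_ancestor(kept, filter_variants(ancestor, params))
annotated = annotate_variants(novel, genome)

print(annotation_table(annotated).to_string(index=False))
nonsyn = select_nonsynonymous(annotated)
print(f"\n{len(evolved)} evolved records -> {len(kept)} pass filters -> "
      f"{len(novel)} novel vs ancestor -> {len(nonsyn)} nonsynonymous")
# Silent changes keep the amino acid; missense swaps it; nonsense gains a
# stop (X). Sub-threshold records (qual <= 95 or depth > 300) were dropped
# before subtraction, mirroring the sequencing-analysis filters.
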