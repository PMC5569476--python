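"""Design a spaced genotyping panel from a synthetic candidate universe.

Generates candidates with planted filter violations, runs the full design
cascade (MAF, accuracy, repeats, probe flanks, heterozygosity, uniqueness,
design score, spacing) and prints the attrition report plus the per-chromosome
density summary.
"""

import snparray as sa
from snparray.simulate import DEFAULT_LAYOUT, CandidateSimConfig, simulate_candidate_set

cands, repeats, neighbors, features, truth = simulate_candidate_set(
    CandidateSimConfig(n_markers=2000), seed=7)

panel, report = sa.design_panel(cands, repeat_mask=repeats,
                                neighbor_variants=neighbors, features=features)

print("filter cascade attrition (input -> removed -> surviving):")
print(report.to_string(index=False))

summary = sa.summarize_panel(panel, DEFAULT_LAYOUT)
print("\nper-chromosome density (avg distance = length / marker count):")
print(summary.per_chromosome.to_string(index=False))
print(f"\npanel: {summary.n_total} markers, "
      f"one every {summary.avg_distance_kb} Kb genome-wide")
print("\nsubgenome shares (% of panel):")
print(summary.subgenomes.to_string(index=False))
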