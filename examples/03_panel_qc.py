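"""Panel evaluation: replicates, a parent/F1 trio, and subpopulation summaries.

Builds a small genotyped panel with a technical replicate and a Mendelian F1,
then prints the concordance, trio-verification and per-group polymorphism
statistics a QC report would contain.
"""

import pandas as pd

import snparray as sa
from snparray.simulate import (PopulationConfig, simulate_f1,
                               simulate_population_genotypes)

gm, truth = simulate_population_genotypes(
    PopulationConfig(n_samples=60, n_markers=800, n_subpops=3, fst=0.25,
                     duplicate_sample=True, seed=23))
gm = simulate_f1(gm, "s0002", "s0003", f1_name="F1", seed=23)

rep = sa.sample_concordance(gm, "s0000", "s0001")
print(f"technical replicates: {rep.similarity_pct:.2f}% identical over "
      f"{rep.n_co_called} co-called loci")

pair = sa.pairwise_polymorphic_rate(gm, "s0002", "s0003")
print(f"polymorphic rate between the two parents: {pair:.2f}%")

trio = sa.verify_f1_heterozygosity(gm, "s0002", "s0003", "F1")
print(f"trio verification: {trio.verification_pct:.2f}% of "
      f"{trio.n_expected} expected heterozygous loci are AB in the F1")

meta = pd.DataFrame({"group": truth.subpop.map(lambda i: f"pop{i}")})
meta.loc["F1", "group"] = "pop0"
print("\nper-group polymorphism (counts of segregating markers):")
print(sa.subpopulation_summary(gm, meta).to_string(index=False))
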