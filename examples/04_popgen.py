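"""Population structure: 1-IBS distances, NJ tree, PCA and LD decay.

Simulates three subpopulations, builds the identity-by-state distance matrix
and neighbor-joining tree, checks that the subpopulations come out
monophyletic, and reports PCA variance and the LD half-maximum decay distance.
"""

import snparray as sa
from snparray.simulate import PopulationConfig, simulate_population_genotypes

gm, truth = simulate_population_genotypes(
    PopulationConfig(n_samples=45, n_markers=600, n_subpops=3, fst=0.2, seed=31))

dm = sa.ibs_distance_matrix(gm)
print(f"mean between-sample 1-IBS distance: {dm.values.sum() / (45 * 44):.4f}")

tree = sa.neighbor_joining_tree(dm)
bp = tree.to_biopython()
# unrooted splits: a clade's leaf set or its complement
all_samples = frozenset(map(str, gm.samples))
splits = set()
for c in bp.get_nonterminals():
    leafset = frozenset(t.name for t in c.get_terminals())
    splits.update({leafset, all_samples - leafset})
for sp in range(3):
    members = frozenset(truth.subpop[truth.subpop == sp].index)
    print(f"subpopulation {sp} forms one branch of the NJ tree: {members in splits}")

pca = sa.pca_coordinates(gm, n_components=4)
print("PCA variance explained:",
      ", ".join(f"PC{i+1} {v:.1%}" for i, v in enumerate(pca.variance_explained)))

# LD needs linkage: rebuild the population from shared founder haplotypes
gm_ld, truth_ld = simulate_population_genotypes(
    PopulationConfig(n_samples=100, n_markers=60, n_subpops=1,
                     ld_founders=4, recomb_per_bp=1e-5,
                     marker_spacing_bp=5_000, seed=31))
ld = sa.ld_statistics(gm_ld, truth_ld.positions, max_dist=300_000,
                      bin_width=20_000)
print(f"LD pairs measured: {len(ld.pairs)}; "
      f"half-maximum decay distance: {ld.decay_distance_bp / 1000:.0f} Kb")
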