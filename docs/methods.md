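# Methods

This note documents the models, the numerical choices and the open design
decisions behind `snparray`, and what the synthetic-data generator does and
does not emulate.

## Array design

Candidates enter as a manifest of putative intraspecific SNPs with
per-locus quality fields (MAF, heterozygosity rate, genotype accuracy, assay
design score, multi-mapping flag).  The hard-filter cascade runs in a fixed
order — MAF → accuracy → repeat regions → probe flanks → heterozygosity →
uniqueness — so attrition reports are reproducible; the rules themselves are
order-independent (the survivor set is a pure intersection), which the tests
verify via batching invariance and idempotence.  Defaults: MAF ≥ 0.1,
accuracy > 0.9912, no other variant within 50 bp of the site, heterozygosity
< 0.15, design score > 0.7 (genic) / > 0.9 (intergenic), inter-marker gap
> 2100 bp.  The accuracy field is consumed as an input; how it is derived
from re-sequencing data is upstream of this package.  "Uniqueness" removes
multi-mapped loci — on a polyploid reference these are the probes confounded
by homoeologous or paralogous copies.

Coordinates are 1-based inclusive internally (VCF/GFF convention); BED input
is converted at the reader boundary.  The spacing constraint is interpreted
as the distance between **adjacent selected markers**: in `max_count` mode a
left-to-right greedy scan keeps the maximum achievable number per chromosome
(optimal for this 1-D packing problem, verified against a DP oracle); in
`score_priority` mode markers are admitted in descending design score subject
to the gap.  Ties break deterministically by (position, id).

Panel summaries report the average inter-marker distance as chromosome length
divided by marker count (not count − 1); at one-decimal Kb rounding the two
conventions agree and the simpler one is fixed.  Gap-histogram default bins
are <10, 10–20, 20–30, 30–40, 40–50 and >50 Kb.  Shares are percentages at
two decimals.  Genomic context uses precedence UTR > exon > intron inside a
gene span; a sub-feature lying outside its parent gene is ignored with a
warning.

## Genotype calling

Genotype classes separate along theta, so the model is a one-dimensional
Gaussian mixture on theta; NormR is used only to gate no-signal samples
(NormR < 0.2 → NG) out of fitting and calling.  k ∈ {1..5} is chosen by
minimum BIC; EM is initialized by k-means++ with three starts under a fixed
random state (quantile seeding collides when one genotype class holds most
samples), making fits deterministic given the seed.  Components lighter than
2 % of samples are removed by refitting with one fewer component.

Adjustment mirrors manual curation of polyploid array data.  Adjacent
clusters closer than `merge_delta_theta = 0.15` merge (closest pair first,
weighted moment matching) until none qualify; 0.15 is chosen to merge
sub-cluster artifacts while keeping the canonical five-class ladder (spacing
≈ 0.23) intact.  A model still holding more than three clusters is a true
tetraploid ladder: it is flagged `polyploid_complex` and collapsed to three
clusters by merging its closest adjacent pairs, preferring off-center pairs
on ties so the homozygote-side classes (AAAA/AAAB, ABBB/BBBB) coalesce first
and every called sample gets a diploidized AA/AB/BB label — the same
collapse a curator performs.  Cluster labels come from a monotone min-cost
assignment of sorted cluster means to the anchors 0/0.5/1 (diploid) and
0.05/0.275/0.5/0.725/0.95 (tetraploid annotation).

Calling assigns the nearest cluster's label unless the standardized theta
distance exceeds 4 cluster standard deviations (off-cluster → `--`).  The
cluster sd is floored at 0.02 for this standardization so near-noise-free
clusters keep a finite capture radius.  Call rate counts AA/AB/BB only; NG
and `--` both reduce it (conservative).  Locus patterns: failed (all
missing), polyploid_adjusted (any merge), partial_ng (any NG), else
monomorphic / two_cluster / three_cluster by k.

## Panel QC

All QC denominators treat NG and `--` as uncalled.  Pairwise similarity is
the identical-call share over loci where both samples carry definite calls;
the polymorphic rate between two accessions is its complement.  Trio
verification takes loci where the parents are opposite homozygotes and all
three samples are called, and reports the share at which the F1 is AB.  MAF
comes from allele counts (AA → 2 ref, AB → 1+1, BB → 2 alt); a marker is
polymorphic within a sample set iff its MAF there exceeds zero.

## Population genetics

Per-locus IBS between diploidized genotypes is the shared-allele fraction
(1, 0.5 or 0); the distance is 1 − mean IBS over co-called loci.  Neighbor
joining follows the Saitou–Nei Q-criterion; exact Q ties break by the
lexicographically smallest pair of node labels, and a negative branch length
is clamped to zero with the deficit moved to the sibling edge so the joined
pair's mutual distance is preserved.  On additive inputs the reconstruction
is exact (tested on random additive trees up to 12 taxa, topology and path
lengths).

PCA operates on the samples × markers dosage matrix, mean-imputed per marker
and mean-centered (unit-variance scaling optional); component signs are fixed
by making the largest-magnitude sample coordinate positive.

Array data are unphased, so r² is the composite (dosage-correlation) form
over pairwise-complete samples; D′ uses EM haplotype-frequency estimation in
which only the double-heterozygote class is phase-ambiguous.  The decay curve
is the mean r² per physical-distance bin (default 10 kb), smoothed by a
centered 3-bin rolling mean; the decay distance is the smallest bin midpoint
at which the smoothed curve falls to half its maximum — a common convention,
not the only one.  It is +inf when LD has not decayed that far within the
window and NaN when there is no curve.

## GWAS

K is the VanRaden genomic relationship matrix (centered-dosage cross-product
over 2Σp(1−p), mean-imputed missing dosages — PSD by construction).  Q
defaults to the top (k−1) principal components plus an intercept: admixture
proportions for k ancestral populations sum to one and span k−1 dimensions,
so PCs substitute for them; an externally computed Q can be supplied.

Variance components are estimated by REML with the parameterization
V = σ²g (K + δI): eigendecompose K once, rotate y and the fixed effects,
profile the restricted likelihood over log δ (coarse grid + bounded Brent,
deterministic), and reuse the null-model δ for every marker (P3D).  Each
marker is then a generalized-least-squares regression in the rotated,
weighted space; the Wald t uses the per-marker residual variance with
n − p − 1 degrees of freedom, which makes the scan collapse exactly to
ordinary least squares when K = I.  Exact per-marker REML is available
behind a flag, as is leave-one-chromosome-out (LOCO) kinship, which prevents
the tested marker's own signal from being absorbed into the polygenic term.

The Bonferroni threshold is 1/n reported at two significant figures; the
fixed reporting threshold defaults to 1×10⁻⁵.  Candidate regions expand each
significant SNP by ±500 kb, clip to the chromosome, merge overlapping
same-chromosome intervals, and report bounds in Mb at two decimals, listing
genes whose spans intersect the region.

## Synthetic data

The generator supplies every input the pipeline needs, with truth labels.

* **Candidate sets**: uniform marker placement (≥10 kb apart so planted
  flanking variants cannot collide with other candidates); disjoint planted
  violation classes per filter stage; a repeat mask, neighbor-variant list
  and a gene/exon/UTR annotation consistent with the planted genic flags.
* **Populations**: Balding–Nichols — ancestral frequency uniform on the MAF
  bounds, subpopulation frequency Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst),
  Hardy–Weinberg within subpopulation; Fst = 0 and 1 handled as the no-drift
  and fixation limits.  Options: missing calls, a duplicated sample
  (technical replicate), full-sib families (unlinked-locus Mendelian
  sampling from founder pairs, expected relatedness ½), and LD via Markov
  founder-haplotype copying (switch probability 1 − exp(−r·gap)).
* **Intensities**: theta ~ N(class mean, sd) truncated to [0, 1], class
  means 0.05/0.50/0.95 (five-cluster mode inserts 0.275/0.725); NormR
  log-normal for called samples and below the NG floor for planted NG
  samples.  The class means are conventions chosen to be symmetric and
  well-separated; real instruments print no canonical values.
* **Trios and phenotypes**: F1 receives one allele from each parent
  (deterministic AB at opposite homozygotes); phenotype = μ + β·dosage +
  polygenic + noise, each component empirically scaled so realized variance
  fractions hit the target h² components (β from h²_snp and the causal's
  empirical dosage variance; polygenic as a sum of small random marker
  effects, hence covariance proportional to K).

What the generator does **not** emulate: real ascertainment bias of array
content, instrument-specific normalization artifacts, linkage maps beyond
the simple copying model, inbreeding/selfing, genotyping error correlated
with probe chemistry, and any particular crop's breeding history.  Green
tests therefore demonstrate algorithmic correctness and statistical behavior
under the stated models, not performance on any real accession panel.

## Problem sizes in the test suite

Tests run on deliberately small instances chosen to make each property
measurable: filter-cascade oracles on 1,000 random instances of ≤20
candidates; caller accuracy on ~12,000 calls at theta sd 0.05; NJ on trees of
≤12 taxa; null mixed-model calibration on one 21,000-marker × 200-sample
scan; causal-SNP power on 50 replicates of a 300-sample × 800-marker scan
over eight chromosomes (100 markers each, unstructured population, LOCO
kinship).  On that power benchmark the scan's measured true power for the
planted SNP (h²_snp = 0.1, MAF 0.3, polygenic h² = 0.3, p < 1×10⁻⁵) is 0.90
over 450 independent replicates; an oracle GLS given the true variance
components achieves 0.86 on the same draws, because the polygenic background
of unrelated samples is statistically inseparable from noise — the scan
operates at the information ceiling of these conditions, and individual
50-replicate batches fluctuate around it.

## Known limitations

* The caller fits theta only; markers whose classes separate mainly in NormR
  (rare) are not modeled beyond the NG gate.
* D′ assumes biallelic loci and random mating within the sample set handed
  to it; applying it across pooled subpopulations mixes haplotype pools.
* The MLM assumes a single random effect with covariance K; dominance,
  epistasis and marker-by-environment terms are out of scope.
* NJ is exact for additive distances but, like all NJ implementations, has
  no optimality guarantee on noisy matrices; no bootstrap support is
  computed.
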