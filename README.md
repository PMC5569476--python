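# snparray

A toolkit for building and using intraspecific SNP genotyping arrays on
polyploid genomes.  It covers the full life cycle of an array experiment:

1. **Design** (`snparray.selection`) — filter re-sequencing candidates through
   the standard hard-filter cascade (MAF, genotype accuracy, repeat regions,
   clean 50 bp probe flanks, heterozygosity, mapping uniqueness), apply the
   assay design-score rule (stricter outside genes), and select a panel whose
   adjacent markers are more than a minimum gap apart; summarize the panel's
   per-chromosome density, subgenome shares and genic/intergenic composition.
2. **Genotype calling** (`snparray.calling`) — call AA/AB/BB from normalized
   two-channel intensities (theta = allele-contrast angle, NormR = total
   signal) with a 1-D Gaussian mixture on theta, BIC model selection up to
   five components, and polyploid cluster adjustment: an allotetraploid locus
   can show an AAAA/AAAB/AABB/ABBB/BBBB ladder whose close pairs are merged
   back onto diploidized calls.  Samples without signal are flagged NG;
   off-cluster samples stay uncalled (`--`).
3. **Panel QC** (`snparray.qc`) — call rates, MAF and polymorphism summaries
   by subpopulation, replicate concordance, pairwise polymorphic rates, and
   parent/F1 trio verification (share of opposite-homozygote parental loci
   called heterozygous in the F1).
4. **Population genetics** (`snparray.popgen`) — 1−IBS distance matrices,
   Saitou–Nei neighbor-joining trees (Newick), PCA of the dosage matrix, and
   LD statistics: composite r² from dosage correlation, D′ from EM haplotype
   frequencies, the binned decay curve and its half-maximum decay distance.
5. **GWAS** (`snparray.gwas`) — the Q+K mixed linear model

   y = μ + Qv + xβ + u + e,  u ~ N(0, σ²g·K),  e ~ N(0, σ²e·I)

   with VanRaden kinship K, principal-component structure covariates Q, REML
   variance components via spectral decomposition (P3D by default, exact
   per-marker REML and leave-one-chromosome-out kinship behind flags), Wald
   tests per marker, Bonferroni/fixed significance thresholds, and merged
   ±500 Kb candidate regions with gene lists.
6. **Synthetic data** (`snparray.simulate`) — Balding–Nichols structured
   populations (optionally with founder-haplotype LD or full-sib families),
   intensity matrices emulating the canonical cluster patterns, trios, and
   phenotypes with a planted causal SNP — all with ground truth, so every
   downstream module is testable without real array data.

The library API is the primary interface (see `examples/`, one script per
capability); a thin `snparray` CLI wraps it with `design`, `call`, `qc`,
`popgen`, `gwas` and `simulate` subcommands.

## Worked example

`examples/05_gwas.py` simulates 300 samples × 800 markers over eight
chromosomes, plants a causal SNP explaining 10 % of trait variance on a 30 %
polygenic background, and scans with the LOCO Q+K mixed model:

```
planted causal SNP: m00133 (beta=0.513)
scan minimum:       m00133 (-log10 p = 7.51, effect = 0.457)
thresholds: Bonferroni 1/n = 0.0015, reporting = 1e-05
candidate region sim2:0.0-0.84 Mb (1 significant SNPs)
```

The scan's strongest association is the planted SNP; its estimated allele
effect (0.457) approaches the planted β, `-log10 p = 7.51` clears the fixed
reporting threshold of 1×10⁻⁵, and the ±500 Kb window around the peak becomes
the candidate region a gene search would use.  Similarly,
`examples/01_design_panel.py` prints the stage-by-stage attrition of the
design cascade (each planted violation class is removed at exactly its stage)
and a density table in which the average marker spacing per chromosome equals
chromosome length divided by marker count.

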