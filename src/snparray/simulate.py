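"""Synthetic data with full ground truth for every other module.

Four generators cover the toolkit's input universe:

* candidate SNP sets with planted filter violations (repeat overlap, dirty
  probe flanks, excess heterozygosity, low design score, multi-mapping) plus
  the matching repeat mask, neighbor-variant list and gene annotation;
* structured populations under the Balding-Nichols model (Beta-distributed
  subpopulation allele frequencies around an ancestral frequency,
  parameterized by Fst), with optional LD via founder-haplotype copying;
* two-channel intensities that emulate the canonical cluster patterns of an
  allotetraploid array locus (three diploidized clusters by default, a
  five-class AAAA..BBBB ladder in five-cluster mode, planted NG samples);
* parent/F1 trios and phenotypes with a planted causal SNP and a polygenic
  background scaled to target heritability components.

Every generator takes a seed (or an existing Generator) and returns truth
labels sufficient to score downstream recovery without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import IntensityMatrix
from .genotypes import GenotypeMatrix

DEFAULT_LAYOUT = pd.DataFrame({
    "chrom": ["A01", "A02", "D01", "D02"],
    "length_bp": [100_000_000, 80_000_000, 60_000_000, 65_000_000],
    "subgenome": ["At", "At", "Dt", "Dt"],
})

#: canonical theta class means: diploidized three-cluster and the
#: allotetraploid five-class ladder
THETA_MEANS_3 = {0: 0.05, 1: 0.50, 2: 0.95}
THETA_MEANS_5 = (0.05, 0.275, 0.50, 0.725, 0.95)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# candidate sets for the design pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSimConfig:
    """Planted-violation fractions for the candidate-set generator.

    Violation fractions are disjoint: each affected candidate violates exactly
    one filter, so stage attrition can be checked against truth labels.
    """

    n_markers: int = 1000
    frac_low_maf: float = 0.05
    frac_low_accuracy: float = 0.05
    frac_repeat: float = 0.05
    frac_flanking: float = 0.05
    frac_high_het: float = 0.05
    frac_multi_mapped: float = 0.05
    frac_low_score: float = 0.05
    genic_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        total = (self.frac_low_maf + self.frac_low_accuracy + self.frac_repeat
                 + self.frac_flanking + self.frac_high_het
                 + self.frac_multi_mapped + self.frac_low_score)
        if total > 1.0:
            raise ValueError("violation fractions sum above 1")


def simulate_candidate_set(
    config: CandidateSimConfig | None = None,
    genome_layout: pd.DataFrame | None = None,
    seed=None,
):
    """Candidate manifest + repeat mask + neighbor variants + gene features.

    Returns ``(candidates, repeat_mask, neighbor_variants, features, truth)``
    where truth maps each violation stage to the set of planted candidate ids.
    Candidates are placed uniformly per chromosome (proportional to length),
    at least 10 kb apart so that planted flanking variants never collide with
    other candidates.
    """
    config = config or CandidateSimConfig()
    layout = genome_layout if genome_layout is not None else DEFAULT_LAYOUT
    rng = _rng(seed if seed is not None else config.seed)

    total_len = layout["length_bp"].sum()
    placeable = int((layout["length_bp"] // 10_000).sum())
    if config.n_markers > placeable:
        raise ValueError(f"n_markers={config.n_markers} exceeds placeable positions")

    rows = []
    n_left = config.n_markers
    for i, (_, chrom_row) in enumerate(layout.iterrows()):
        share = chrom_row["length_bp"] / total_len
        n = int(round(config.n_markers * share)) if i < len(layout) - 1 else n_left
        n = min(n, n_left)
        n_left -= n
        grid = np.arange(1, chrom_row["length_bp"] // 10_000) * 10_000
        pos = np.sort(rng.choice(grid, size=n, replace=False))
        for p in pos:
            rows.append({"chrom": chrom_row["chrom"], "pos": int(p)})
    df = pd.DataFrame(rows)
    m = len(df)
    df["id"] = [f"snp{i:06d}" for i in range(m)]
    alleles = np.array(list("ACGT"))
    ra = rng.integers(0, 4, size=m)
    df["ref"] = alleles[ra]
    df["alt"] = alleles[(ra + rng.integers(1, 4, size=m)) % 4]
    df["maf"] = rng.uniform(0.12, 0.5, size=m)
    df["het_rate"] = rng.uniform(0.0, 0.12, size=m)
    df["accuracy"] = rng.uniform(0.9920, 1.0, size=m)
    df["multi_mapped"] = False
    genic = rng.random(m) < config.genic_fraction
    df["design_score"] = np.where(genic, rng.uniform(0.72, 1.0, size=m),
                                  rng.uniform(0.91, 1.0, size=m))

    # disjoint planted violations
    order = rng.permutation(m)
    truth: dict[str, set] = {}
    cursor = 0

    def _take(frac: float) -> np.ndarray:
        nonlocal cursor
        k = int(round(frac * m))
        sel = order[cursor:cursor + k]
        cursor += k
        return sel

    sel = _take(config.frac_low_maf)
    df.loc[df.index[sel], "maf"] = rng.uniform(0.01, 0.0999, size=len(sel))
    truth["maf"] = set(df["id"].iloc[sel])

    sel = _take(config.frac_low_accuracy)
    df.loc[df.index[sel], "accuracy"] = rng.uniform(0.90, 0.9912, size=len(sel))
    truth["accuracy"] = set(df["id"].iloc[sel])

    sel = _take(config.frac_repeat)
    truth["repeat"] = set(df["id"].iloc[sel])
    repeat_rows = [{"chrom": df["chrom"].iloc[i],
                    "start": int(df["pos"].iloc[i]) - 100,
                    "end": int(df["pos"].iloc[i]) + 100} for i in sel]
    repeat_mask = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"])

    sel = _take(config.frac_flanking)
    truth["flanking"] = set(df["id"].iloc[sel])
    neigh_rows = [{"chrom": df["chrom"].iloc[i],
                   "pos": int(df["pos"].iloc[i]) + int(rng.integers(1, 51))}
                  for i in sel]
    neighbor_variants = pd.DataFrame(neigh_rows, columns=["chrom", "pos"])

    sel = _take(config.frac_high_het)
    df.loc[df.index[sel], "het_rate"] = rng.uniform(0.16, 0.5, size=len(sel))
    truth["heterozygosity"] = set(df["id"].iloc[sel])

    sel = _take(config.frac_multi_mapped)
    df.loc[df.index[sel], "multi_mapped"] = True
    truth["uniqueness"] = set(df["id"].iloc[sel])

    sel = _take(config.frac_low_score)
    low = df.index[sel]
    df.loc[low, "design_score"] = np.where(genic[sel],
                                           rng.uniform(0.0, 0.699, size=len(sel)),
                                           rng.uniform(0.0, 0.899, size=len(sel)))
    truth["design_score"] = set(df["id"].iloc[sel])

    # gene features consistent with the planted genic flags: a 5 kb gene with
    # one exon and one UTR around each genic candidate
    feat_rows = []
    for i in np.where(genic)[0]:
        p = int(df["pos"].iloc[i])
        chrom = df["chrom"].iloc[i]
        gid = f"gene_{df['id'].iloc[i]}"
        start, end = max(1, p - 2500), p + 2500
        feat_rows.append({"chrom": chrom, "start": start, "end": end,
                          "ftype": "gene", "gene_id": gid})
        r = rng.random()
        if r < 1 / 3:  # candidate inside the exon
            feat_rows.append({"chrom": chrom, "start": p - 200, "end": p + 200,
                              "ftype": "exon", "gene_id": gid})
        elif r < 2 / 3:  # candidate inside the UTR
            feat_rows.append({"chrom": chrom, "start": p - 100, "end": p + 100,
                              "ftype": "UTR", "gene_id": gid})
        else:  # intronic: exon elsewhere in the gene
            feat_rows.append({"chrom": chrom, "start": end - 400, "end": end - 100,
                              "ftype": "exon", "gene_id": gid})
    features = pd.DataFrame(feat_rows,
                            columns=["chrom", "start", "end", "ftype", "gene_id"])
    truth["genic_ids"] = set(df["id"].iloc[np.where(genic)[0]])

    cols = ["id", "chrom", "pos", "ref", "alt", "maf", "het_rate", "accuracy",
            "design_score", "multi_mapped"]
    return df[cols].reset_index(drop=True), repeat_mask, neighbor_variants, features, truth


# ---------------------------------------------------------------------------
# structured populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    n_samples: int = 150
    n_markers: int = 2000
    n_subpops: int = 3
    n_chromosomes: int = 1
    fst: float = 0.2
    maf_bounds: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    duplicate_sample: bool = False
    family_size: int = 1            # >1 groups samples into full-sib families
    ld_founders: int = 0            # >0 switches on founder-haplotype copying
    recomb_per_bp: float = 1e-6
    marker_spacing_bp: int = 10_000
    seed: int = 0


@dataclass
class PopulationTruth:
    subpop: pd.Series               # sample -> subpopulation index
    ancestral_freq: np.ndarray      # per marker
    subpop_freq: np.ndarray         # n_subpops x markers
    positions: pd.DataFrame         # marker -> chrom, pos


def simulate_population_genotypes(
    config: PopulationConfig | None = None, seed=None,
) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Balding-Nichols structured genotypes.

    Ancestral alt frequency ~ Uniform(maf_bounds); subpopulation frequency ~
    Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst) (drawn as-is at Fst=0, fixed to 0/1
    with probability p at Fst=1); genotypes Hardy-Weinberg within
    subpopulation.  ``ld_founders > 0`` instead builds each subpopulation from
    that many founder haplotypes with Markov copying (switch probability
    1 - exp(-recomb_per_bp * gap)), creating distance-decaying LD.
    """
    config = config or PopulationConfig()
    rng = _rng(seed if seed is not None else config.seed)
    n, m, s = config.n_samples, config.n_markers, config.n_subpops
    p_anc = rng.uniform(*config.maf_bounds, size=m)

    if config.fst == 0:
        freqs = np.tile(p_anc, (s, 1))
    elif config.fst == 1:
        freqs = (rng.random((s, m)) < p_anc).astype(float)
    else:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        freqs = rng.beta(np.tile(a, (s, 1)), np.tile(b, (s, 1)))

    subpop = np.repeat(np.arange(s), int(np.ceil(n / s)))[:n]
    # markers split evenly over chromosomes, equally spaced within each
    chrom_of = np.minimum(np.arange(m) // max(m // config.n_chromosomes, 1),
                          config.n_chromosomes - 1)
    within = np.zeros(m, dtype=int)
    for c in range(config.n_chromosomes):
        sel = chrom_of == c
        within[sel] = np.arange(sel.sum())
    positions = pd.DataFrame({
        "chrom": [f"sim{c + 1}" for c in chrom_of],
        "pos": (within + 1) * config.marker_spacing_bp,
    }, index=[f"m{i:05d}" for i in range(m)])

    if config.ld_founders > 0:
        dosage = np.zeros((m, n), dtype=float)
        gaps = np.diff(positions["pos"].to_numpy(float), prepend=0.0)
        # a chromosome boundary (position reset) is a free recombination
        p_switch = np.where(gaps < 0, 1.0,
                            1.0 - np.exp(-config.recomb_per_bp * gaps))
        for sp in range(s):
            founders = (rng.random((config.ld_founders, m)) < freqs[sp]).astype(np.int8)
            members = np.where(subpop == sp)[0]
            for hap_round in range(2):
                idx = rng.integers(0, config.ld_founders, size=len(members))
                for k, mark in enumerate(range(m)):
                    switch = rng.random(len(members)) < p_switch[mark]
                    newidx = rng.integers(0, config.ld_founders, size=len(members))
                    idx = np.where(switch, newidx, idx)
                    dosage[mark, members] += founders[idx, mark]
    elif config.family_size > 1:
        # full-sib families: two founders per family drawn from the
        # subpopulation frequencies, sibs by independent Mendelian sampling
        # (unlinked loci), giving expected within-family relatedness 1/2
        dosage = np.zeros((m, n), dtype=float)
        i = 0
        while i < n:
            sp = subpop[i]
            fam = range(i, min(i + config.family_size, n))
            fam = [j for j in fam if subpop[j] == sp]
            p1 = rng.binomial(1, freqs[sp], size=(2, m))  # two alleles per founder
            p2 = rng.binomial(1, freqs[sp], size=(2, m))
            for j in fam:
                a1 = p1[rng.integers(0, 2, size=m), np.arange(m)]
                a2 = p2[rng.integers(0, 2, size=m), np.arange(m)]
                dosage[:, j] = a1 + a2
            i += len(fam)
    else:
        f_per_sample = freqs[subpop, :].T  # markers x samples
        dosage = rng.binomial(2, f_per_sample).astype(float)

    codes = dosage.astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = -2
    if config.duplicate_sample and n >= 2:
        codes[:, 1] = codes[:, 0]
        subpop[1] = subpop[0]

    sample_ids = [f"s{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(pd.DataFrame(codes, index=positions.index, columns=sample_ids))
    truth = PopulationTruth(
        subpop=pd.Series(subpop, index=sample_ids),
        ancestral_freq=p_anc, subpop_freq=freqs, positions=positions,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# array intensities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensitySimConfig:
    theta_sd: float = 0.02
    r_mean: float = 1.0
    r_sigma: float = 0.2            # log-normal sigma of called samples
    ng_rate: float = 0.0
    ng_r_max: float = 0.15          # NG samples draw NormR in [0, ng_r_max]
    five_cluster_markers: tuple = ()
    seed: int = 0


def simulate_intensities(
    gm: GenotypeMatrix,
    config: IntensitySimConfig | None = None,
    seed=None,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Theta/NormR intensities emulating the canonical cluster patterns.

    Called samples draw theta ~ N(class mean, theta_sd) truncated to [0, 1]
    and log-normal NormR; planted NG samples draw NormR below the caller's
    signal floor.  Markers listed in ``five_cluster_markers`` expand their
    genotypes onto the five-class tetraploid ladder (hets split between the
    AAAB/AABB/ABBB classes) to exercise polyploid cluster adjustment.

    Returns the intensity matrix and a truth frame with the per-(marker,
    sample) true class mean and NG flag.
    """
    config = config or IntensitySimConfig()
    rng = _rng(seed if seed is not None else config.seed)
    dosage = gm.dosage().values
    m, n = dosage.shape
    means = np.vectorize(lambda d: THETA_MEANS_3.get(d, np.nan))(dosage)

    five = set(config.five_cluster_markers)
    ladder = np.array(THETA_MEANS_5)
    for i, marker in enumerate(gm.markers):
        if marker not in five:
            continue
        d = dosage[i]
        cls = np.where(d == 0, 0, np.where(d == 2, 4, rng.integers(1, 4, size=n)))
        means[i] = ladder[np.where(np.isnan(d), 0, cls).astype(int)]
        means[i, np.isnan(d)] = np.nan

    theta = np.clip(rng.normal(means, config.theta_sd), 0.0, 1.0)
    norm_r = config.r_mean * rng.lognormal(0.0, config.r_sigma, size=(m, n))
    ng = rng.random((m, n)) < config.ng_rate
    ng |= np.isnan(means)
    norm_r[ng] = rng.uniform(0.0, config.ng_r_max, size=int(ng.sum()))
    theta[np.isnan(theta)] = 0.5

    intensities = IntensityMatrix(
        theta=pd.DataFrame(theta, index=gm.markers, columns=gm.samples),
        norm_r=pd.DataFrame(norm_r, index=gm.markers, columns=gm.samples),
    )
    truth = pd.DataFrame({
        "marker": np.repeat(gm.markers, n),
        "sample": np.tile(gm.samples, m),
        "class_mean": means.ravel(),
        "is_ng": ng.ravel(),
    })
    return intensities, truth


# ---------------------------------------------------------------------------
# trios and phenotypes
# ---------------------------------------------------------------------------

def simulate_f1(gm: GenotypeMatrix, parent1: str, parent2: str,
                f1_name: str = "F1", seed=None) -> GenotypeMatrix:
    """Mendelian F1: one allele from each parent per locus (deterministic AB
    at opposite-homozygote loci); uncalled where either parent is uncalled."""
    rng = _rng(seed)
    p1 = gm.codes[parent1].values
    p2 = gm.codes[parent2].values

    def _gamete(codes):
        g = np.where(codes == 0, 0, np.where(codes == 2, 1, -9))
        het = codes == 1
        g = np.where(het, rng.integers(0, 2, size=len(codes)), g)
        return np.where(codes < 0, -9, g)

    g1, g2 = _gamete(p1), _gamete(p2)
    f1 = np.where((g1 >= 0) & (g2 >= 0), g1 + g2, -2).astype(np.int8)
    calls = gm.codes.copy()
    calls[f1_name] = f1
    return GenotypeMatrix(calls)


@dataclass(frozen=True)
class PhenotypeSimConfig:
    causal_marker: str | None = None  # default: most polymorphic marker
    effect_size: float | None = None  # used directly when h2_snp is None
    h2_snp: float | None = 0.1        # scales the causal effect when set
    h2_polygenic: float = 0.3
    noise_sd: float | None = None     # overrides the h2-derived noise scale
    mu: float = 0.0
    trait: str = "trait"
    seed: int = 0


@dataclass
class PhenotypeTruth:
    causal_marker: str
    beta: float
    realized_h2_snp: float
    realized_h2_polygenic: float
    genetic_values: np.ndarray


def simulate_phenotype(
    gm: GenotypeMatrix,
    config: PhenotypeSimConfig | None = None,
    seed=None,
) -> tuple[pd.Series, PhenotypeTruth]:
    """Phenotype = mu + beta * causal dosage + polygenic term + noise.

    The polygenic term is a sum of small effects over all markers; component
    variances are scaled empirically so the realized variance fractions hit
    the targets (h2_snp for the causal SNP, h2_polygenic for the background;
    the remainder is Gaussian noise — zero when the two sum to one).
    """
    config = config or PhenotypeSimConfig()
    rng = _rng(seed if seed is not None else config.seed)
    dos = gm.dosage()
    col_mean = dos.mean(axis=1)
    X = dos.sub(col_mean, axis=0).fillna(0.0).values.T  # samples x markers

    maf = gm.maf()
    causal = config.causal_marker or maf.idxmax()
    if not (maf[causal] > 0):
        raise ValueError(f"causal marker {causal!r} is monomorphic")
    ci = list(gm.markers).index(causal)
    x = X[:, ci]
    var_x = x.var()

    h2_snp = config.h2_snp
    h2_poly = config.h2_polygenic
    if h2_snp is None:
        beta = float(config.effect_size)
        h2_snp = beta ** 2 * var_x  # on the unit-total-variance scale below
    else:
        beta = float(np.sqrt(h2_snp / var_x))
        if config.effect_size is not None and config.effect_size < 0:
            beta = -beta
    if h2_snp + h2_poly > 1.0 + 1e-12:
        raise ValueError("h2 components exceed 1")

    g_raw = X @ rng.normal(0.0, 1.0, size=X.shape[1]) / np.sqrt(max(X.shape[1], 1))
    g_var = g_raw.var()
    g = g_raw * np.sqrt(h2_poly / g_var) if (h2_poly > 0 and g_var > 0) else np.zeros(len(x))
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
        e = rng.normal(0.0, noise_sd, size=len(x)) if noise_sd > 0 else np.zeros(len(x))
    else:
        # like the genetic components, noise is empirically scaled so the
        # realized variance fractions hit their targets
        noise_var = max(1.0 - h2_snp - h2_poly, 0.0)
        e_raw = rng.normal(0.0, 1.0, size=len(x))
        e = e_raw * np.sqrt(noise_var) / e_raw.std() if noise_var > 0 else np.zeros(len(x))

    y = config.mu + beta * x + g + e
    var_y = y.var()
    truth = PhenotypeTruth(
        causal_marker=str(causal), beta=beta,
        realized_h2_snp=float((beta * x).var() / var_y) if var_y > 0 else float("nan"),
        realized_h2_polygenic=float(g.var() / var_y) if var_y > 0 else float("nan"),
        genetic_values=beta * x + g,
    )
    return pd.Series(y, index=gm.samples, name=config.trait), truth
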