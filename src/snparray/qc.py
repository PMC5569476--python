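"""Panel evaluation: call rates, polymorphism summaries, replicate concordance
and parent/F1 heterozygosity verification.

NG and ``--`` are both treated as uncalled in every denominator here: a
concordance or polymorphic-rate comparison only uses loci where both samples
carry a definite AA/AB/BB call, and a trio locus only counts when parents and
F1 are all called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass
class ConcordanceResult:
    """Pairwise genotype agreement between two samples over co-called loci."""

    sample_a: str
    sample_b: str
    n_co_called: int
    n_identical: int
    similarity_pct: float      # 100 * identical / co-called
    differing_pct: float       # 100 - similarity
    per_chromosome: pd.DataFrame | None = None
    defined: bool = True


@dataclass
class TrioResult:
    """Parent/F1 heterozygosity verification.

    Expected heterozygous loci are those where the two parents carry opposite
    homozygotes (AA x BB) and all three samples are called; verification is
    the share of those loci at which the F1 is AB.
    """

    parent1: str
    parent2: str
    f1: str
    n_expected: int
    n_observed_het: int
    verification_pct: float
    per_locus: pd.DataFrame | None = None  # marker, expected flag, f1 call, pass
    defined: bool = True


def compute_locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, MAF, heterozygosity and polymorphism flag.

    MAF comes from allele counts over called genotypes (AA -> 2 ref, AB -> 1+1,
    BB -> 2 alt); a marker is polymorphic iff MAF > 0.  Markers with zero
    calls are flagged undefined rather than propagating NaN silently.
    """
    if gm.shape[0] == 0 or gm.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    codes = gm.codes.values
    called = codes >= 0
    n_called = called.sum(axis=1)
    call_rate = gm.call_rate(axis="marker")
    maf = gm.maf()
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0,
                       (codes == 1).sum(axis=1) / np.maximum(n_called, 1), np.nan)
    out = pd.DataFrame({
        "call_rate": call_rate,
        "maf": maf,
        "het_rate": het,
        "n_called": n_called,
        "defined": n_called > 0,
    }, index=gm.markers)
    out["polymorphic"] = (out["maf"] > 0).fillna(False)
    return out


def _co_called(gm: GenotypeMatrix, a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for s in (a, b):
        if s not in gm.samples:
            raise KeyError(f"sample {s!r} not in genotype matrix")
    ca = gm.codes[a].values
    cb = gm.codes[b].values
    both = (ca >= 0) & (cb >= 0)
    return ca, cb, both


def sample_concordance(gm: GenotypeMatrix, sample_a: str, sample_b: str,
                       positions: pd.DataFrame | None = None) -> ConcordanceResult:
    """Similarity % between two samples over loci where both are called.

    ``positions`` (marker-indexed, column ``chrom``) adds a per-chromosome
    breakdown.
    """
    ca, cb, both = _co_called(gm, sample_a, sample_b)
    n_co = int(both.sum())
    if n_co == 0:
        return ConcordanceResult(sample_a, sample_b, 0, 0,
                                 float("nan"), float("nan"), defined=False)
    ident = (ca == cb) & both
    n_id = int(ident.sum())
    sim = 100.0 * n_id / n_co
    per_chrom = None
    if positions is not None:
        chrom = positions.loc[gm.markers, "chrom"].to_numpy()
        rows = []
        for c in pd.unique(chrom):
            sel = (chrom == c) & both
            n = int(sel.sum())
            k = int((ident & sel).sum())
            rows.append({"chrom": c, "n_co_called": n, "n_identical": k,
                         "similarity_pct": 100.0 * k / n if n else float("nan")})
        per_chrom = pd.DataFrame(rows)
    return ConcordanceResult(sample_a, sample_b, n_co, n_id, sim, 100.0 - sim,
                             per_chromosome=per_chrom)


def pairwise_polymorphic_rate(gm: GenotypeMatrix, sample_a: str, sample_b: str) -> float:
    """Percentage of co-called loci at which the two samples differ.

    The complement of :func:`sample_concordance`'s similarity.
    """
    res = sample_concordance(gm, sample_a, sample_b)
    return res.differing_pct


def verify_f1_heterozygosity(gm: GenotypeMatrix, parent1: str, parent2: str,
                             f1: str) -> TrioResult:
    """Share of expected heterozygous loci that the F1 actually calls AB."""
    for s in (parent1, parent2, f1):
        if s not in gm.samples:
            raise KeyError(f"sample {s!r} not in genotype matrix")
    p1 = gm.codes[parent1].values
    p2 = gm.codes[parent2].values
    c1 = gm.codes[f1].values
    all_called = (p1 >= 0) & (p2 >= 0) & (c1 >= 0)
    opposite_hom = ((p1 == 0) & (p2 == 2)) | ((p1 == 2) & (p2 == 0))
    expected = all_called & opposite_hom
    n_exp = int(expected.sum())
    observed = expected & (c1 == 1)
    n_obs = int(observed.sum())
    per_locus = pd.DataFrame({
        "expected": expected,
        "f1_call": gm.codes[f1].map({0: "AA", 1: "AB", 2: "BB", -1: "NG", -2: "--"}),
        "pass": observed,
    }, index=gm.markers)
    if n_exp == 0:
        return TrioResult(parent1, parent2, f1, 0, 0, float("nan"),
                          per_locus=per_locus, defined=False)
    return TrioResult(parent1, parent2, f1, n_exp, n_obs, 100.0 * n_obs / n_exp,
                      per_locus=per_locus)


def subpopulation_summary(gm: GenotypeMatrix, metadata: pd.DataFrame,
                          maf_cuts: tuple[float, ...] = (0.05, 0.1)) -> pd.DataFrame:
    """Per-group polymorphic-SNP and MAF-threshold counts, plus an overall row.

    ``metadata`` is sample-indexed with a ``group`` column; group statistics
    are computed within the group's members only.  MAF-threshold counts nest:
    count(MAF > 0.1) <= count(MAF > 0.05) <= polymorphic count.
    """
    missing = set(gm.samples) - set(metadata.index)
    if missing:
        raise ValueError(f"samples without group label: {sorted(missing)}")
    rows = []

    def _row(name: str, samples: list[str], n_acc: int):
        sub = gm.subset(samples=samples)
        maf = sub.maf()
        row = {"group": name, "n_accessions": n_acc,
               "polymorphic": int((maf > 0).sum())}
        for cut in maf_cuts:
            row[f"maf_gt_{cut:g}"] = int((maf > cut).sum())
        rows.append(row)

    groups = metadata.loc[list(gm.samples)].groupby("group")
    for name, sub in groups:
        members = list(sub.index)
        if len(members) < 2:
            warnings.warn(f"group {name!r} has fewer than 2 samples")
        _row(str(name), members, len(members))
    _row("Total", list(gm.samples), gm.shape[1])
    return pd.DataFrame(rows)
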