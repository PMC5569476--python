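"""SNP array design: candidate filter cascade, spacing selection, panel summaries.

The design pipeline mirrors how intraspecific genotyping arrays are assembled
from re-sequencing candidates on a polyploid reference: a hard-filter cascade
(MAF, genotyping accuracy, repeat regions, clean probe flanks, heterozygosity,
mapping uniqueness), an assay design-score rule that is stricter outside genes,
and a per-chromosome spacing selection that keeps adjacent markers more than a
minimum gap apart.  Panel summaries report the per-chromosome density table,
subgenome shares, the inter-marker gap histogram and the genic/intergenic
breakdown that characterize the finished panel.

Coordinates are 1-based inclusive throughout (VCF/GFF convention); BED input is
converted at the reader boundary (:mod:`snparray.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fixed cascade order for :func:`apply_hard_filters`
STAGE_ORDER = ("maf", "accuracy", "repeat", "flanking", "heterozygosity", "uniqueness")

#: columns a candidate manifest must provide
CANDIDATE_COLUMNS = (
    "id", "chrom", "pos", "ref", "alt",
    "maf", "het_rate", "accuracy", "design_score", "multi_mapped",
)

#: default gap-histogram bin edges, Kb
DEFAULT_GAP_BINS_KB = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate filter cascade and spacing rule.

    Defaults are the published array-design settings: MAF > 0.1, genotype
    accuracy > 99.12%, no neighboring variant within 50 bp of the probe site,
    heterozygosity < 15%, design score > 0.7 in genes and > 0.9 elsewhere,
    and > 2100 bp between adjacent selected markers.
    """

    maf_min: float = 0.1
    accuracy_min: float = 0.9912
    flank_bp: int = 50
    het_max: float = 0.15
    score_genic_min: float = 0.7
    score_intergenic_min: float = 0.9
    min_gap_bp: int = 2100
    drop_multi_mapped: bool = True

    def __post_init__(self):
        for name, lo, hi in (
            ("maf_min", 0.0, 0.5),
            ("accuracy_min", 0.0, 1.0),
            ("het_max", 0.0, 1.0),
            ("score_genic_min", 0.0, 1.0),
            ("score_intergenic_min", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.min_gap_bp <= 0:
            raise ValueError("min_gap_bp must be > 0")


# ---------------------------------------------------------------------------
# interval helpers (1-based inclusive internally)
# ---------------------------------------------------------------------------

def _check_intervals(intervals: pd.DataFrame, what: str) -> None:
    bad = intervals[intervals["end"] < intervals["start"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"malformed {what} interval on {row['chrom']}: "
            f"end {int(row['end'])} < start {int(row['start'])}"
        )


def _check_chromosomes(df: pd.DataFrame, known: set[str], what: str) -> None:
    unknown = set(df["chrom"].unique()) - known
    if unknown:
        raise ValueError(f"unknown chromosome {sorted(unknown)[0]!r} in {what}")


def _in_intervals(chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of 1-based positions in a set of 1-based inclusive intervals."""
    hit = np.zeros(len(pos), dtype=bool)
    for c, sub in intervals.groupby("chrom"):
        sel = chrom == c
        if not sel.any():
            continue
        # merge overlapping intervals then binary-search
        iv = sub.sort_values("start")[["start", "end"]].to_numpy(float)
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        inside[ok] = pos[sel][ok] <= ends[idx[ok]]
        hit[sel] = inside
    return hit


def _near_variant(chrom: np.ndarray, pos: np.ndarray,
                  variants: pd.DataFrame, flank_bp: int) -> np.ndarray:
    """True where another variant lies within ``flank_bp`` of the site.

    A variant at the exact candidate position is taken to be the candidate
    itself and does not count.
    """
    hit = np.zeros(len(pos), dtype=bool)
    for c, sub in variants.groupby("chrom"):
        sel = chrom == c
        if not sel.any():
            continue
        vp = np.sort(sub["pos"].to_numpy(float))
        p = pos[sel]
        lo = np.searchsorted(vp, p - flank_bp, side="left")
        hi = np.searchsorted(vp, p + flank_bp, side="right")
        n_window = hi - lo
        # subtract self-hits (variants at the exact same position)
        n_self = (np.searchsorted(vp, p, side="right")
                  - np.searchsorted(vp, p, side="left"))
        hit[sel] = (n_window - n_self) > 0
    return hit


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def apply_hard_filters(
    candidates: pd.DataFrame,
    config: FilterConfig | None = None,
    repeat_mask: pd.DataFrame | None = None,
    neighbor_variants: pd.DataFrame | None = None,
    known_chromosomes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the hard-filter cascade in its fixed order.

    Stages (fixed order): MAF >= maf_min, accuracy > accuracy_min, outside the
    repeat mask, no other variant within flank_bp, het_rate < het_max, and
    (if configured) not multi-mapped.

    Parameters
    ----------
    candidates
        Candidate manifest with :data:`CANDIDATE_COLUMNS`.
    repeat_mask
        Intervals (chrom, start, end), 1-based inclusive.
    neighbor_variants
        Positions (chrom, pos) of all known SNPs/InDels in the source data.

    Returns
    -------
    (survivors, report)
        Survivors in input order, and a stage-by-stage attrition report with
        columns ``stage, n_input, n_removed, n_surviving``.
    """
    config = config or FilterConfig()
    known = known_chromosomes or set(candidates["chrom"].unique())
    if repeat_mask is not None and len(repeat_mask):
        _check_intervals(repeat_mask, "repeat mask")
        if len(candidates):
            _check_chromosomes(repeat_mask, known, "repeat mask")
    if neighbor_variants is not None and len(neighbor_variants) and len(candidates):
        _check_chromosomes(neighbor_variants, known, "neighbor variants")

    df = candidates
    rows = []

    def _stage(name: str, keep: np.ndarray):
        nonlocal df
        n_in = len(df)
        df = df.loc[keep]
        rows.append({"stage": name, "n_input": n_in,
                     "n_removed": int(n_in - len(df)),
                     "n_surviving": len(df)})

    _stage("maf", df["maf"].to_numpy() >= config.maf_min if len(df) else np.zeros(0, bool))
    _stage("accuracy", df["accuracy"].to_numpy() > config.accuracy_min if len(df) else np.zeros(0, bool))

    if repeat_mask is not None and len(repeat_mask) and len(df):
        inside = _in_intervals(df["chrom"].to_numpy(), df["pos"].to_numpy(float), repeat_mask)
        _stage("repeat", ~inside)
    else:
        _stage("repeat", np.ones(len(df), dtype=bool))

    if neighbor_variants is not None and len(neighbor_variants) and len(df):
        near = _near_variant(df["chrom"].to_numpy(), df["pos"].to_numpy(float),
                             neighbor_variants, config.flank_bp)
        _stage("flanking", ~near)
    else:
        _stage("flanking", np.ones(len(df), dtype=bool))

    _stage("heterozygosity", df["het_rate"].to_numpy() < config.het_max if len(df) else np.zeros(0, bool))

    if config.drop_multi_mapped and len(df):
        _stage("uniqueness", ~df["multi_mapped"].to_numpy(bool))
    else:
        _stage("uniqueness", np.ones(len(df), dtype=bool))

    report = pd.DataFrame(rows, columns=["stage", "n_input", "n_removed", "n_surviving"])
    return df.copy(), report


def apply_design_score_rule(candidates: pd.DataFrame,
                            config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep genic candidates with score > genic threshold, intergenic with
    score > the stricter intergenic threshold."""
    config = config or FilterConfig()
    if "region_class" not in candidates.columns:
        raise ValueError("candidates lack region_class; run annotate_snp_context first")
    missing = candidates.loc[candidates["design_score"].isna(), "id"]
    if len(missing):
        raise ValueError(f"missing design_score for: {', '.join(map(str, missing))}")
    score = candidates["design_score"].to_numpy(float)
    genic = candidates["region_class"].to_numpy() == "genic"
    keep = np.where(genic, score > config.score_genic_min,
                    score > config.score_intergenic_min)
    return candidates.loc[keep].copy()


# ---------------------------------------------------------------------------
# spacing selection
# ---------------------------------------------------------------------------

def select_spaced_markers(candidates: pd.DataFrame, min_gap_bp: int = 2100,
                          mode: str = "max_count") -> pd.DataFrame:
    """Select a per-chromosome marker subset with all adjacent gaps > min_gap_bp.

    ``max_count`` keeps the largest achievable number per chromosome (greedy
    left-to-right scan, which is optimal for this one-dimensional packing);
    ``score_priority`` admits markers in descending design_score subject to the
    gap constraint.  Ties break deterministically by (position, id).
    """
    if mode not in ("max_count", "score_priority"):
        raise ValueError(f"unknown mode {mode!r}")
    dup = candidates.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = candidates.loc[dup].iloc[0]
        raise ValueError(f"duplicate (chromosome, position): {row['chrom']}:{int(row['pos'])}")

    kept_idx = []
    for _, sub in candidates.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "id"], kind="mergesort")
        pos = sub["pos"].to_numpy(float)
        if mode == "max_count":
            last = -np.inf
            for i in range(len(sub)):
                if pos[i] - last > min_gap_bp:
                    kept_idx.append(sub.index[i])
                    last = pos[i]
        else:
            order = sub.sort_values(["design_score", "pos", "id"],
                                    ascending=[False, True, True],
                                    kind="mergesort").index
            taken: list[float] = []
            for idx in order:
                p = float(candidates.at[idx, "pos"])
                j = np.searchsorted(taken, p)
                if j > 0 and p - taken[j - 1] <= min_gap_bp:
                    continue
                if j < len(taken) and taken[j] - p <= min_gap_bp:
                    continue
                taken.insert(j, p)
                kept_idx.append(idx)

    panel = candidates.loc[kept_idx].sort_values(["chrom", "pos"], kind="mergesort")
    return panel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# genomic-context annotation
# ---------------------------------------------------------------------------

def annotate_snp_context(candidates: pd.DataFrame,
                         features: pd.DataFrame) -> pd.DataFrame:
    """Fill region_class (genic/intergenic) and feature (UTR/exon/intron/none).

    ``features`` has columns chrom, start, end, ftype in {gene, exon, UTR},
    gene_id, with 1-based inclusive coordinates.  Within a gene the precedence
    is UTR > exon > intron.  A non-gene feature falling outside its parent
    gene span is ignored with a warning.
    """
    df = candidates.copy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(float)

    genes = features[features["ftype"] == "gene"]
    spans = genes.set_index("gene_id")[["chrom", "start", "end"]] if len(genes) else None
    sub_feats = {"UTR": [], "exon": []}
    for _, f in features[features["ftype"].isin(("UTR", "exon"))].iterrows():
        gid = f.get("gene_id")
        if spans is not None and gid in spans.index:
            g = spans.loc[gid]
            if f["start"] < g["start"] or f["end"] > g["end"] or f["chrom"] != g["chrom"]:
                warnings.warn(
                    f"{f['ftype']} interval {f['chrom']}:{int(f['start'])}-{int(f['end'])} "
                    f"lies outside its parent gene {gid}; ignored")
                continue
        sub_feats[f["ftype"]].append(f)

    in_gene = _in_intervals(chrom, pos, genes) if len(genes) else np.zeros(len(df), bool)
    in_utr = (_in_intervals(chrom, pos, pd.DataFrame(sub_feats["UTR"]))
              if sub_feats["UTR"] else np.zeros(len(df), bool))
    in_exon = (_in_intervals(chrom, pos, pd.DataFrame(sub_feats["exon"]))
               if sub_feats["exon"] else np.zeros(len(df), bool))

    feature = np.where(~in_gene, "none",
                       np.where(in_utr, "UTR", np.where(in_exon, "exon", "intron")))
    df["region_class"] = np.where(in_gene, "genic", "intergenic")
    df["feature"] = feature
    return df


# ---------------------------------------------------------------------------
# panel summaries
# ---------------------------------------------------------------------------

def share_percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage share rounded for reporting (NaN on a zero denominator)."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def average_spacing_kb(n_markers: int, length_kb: float, decimals: int = 1) -> float:
    """Average inter-marker distance = chromosome length / marker count, in Kb.

    Undefined (NaN) for a chromosome with zero markers.
    """
    if n_markers == 0:
        return float("nan")
    return round(length_kb / n_markers, decimals)


@dataclass
class PanelSummary:
    """Marker-density and composition summary of a selected panel."""

    per_chromosome: pd.DataFrame   # chrom, n_snps, length_kb, avg_distance_kb, largest_gap_kb
    subgenomes: pd.DataFrame       # subgenome, n_snps, length_kb, avg_distance_kb, share_pct
    gap_histogram: pd.DataFrame    # bin label, count, share_pct
    regions: pd.DataFrame          # region_class, count, share_pct
    features: pd.DataFrame         # feature within genic, count, share_pct
    n_total: int = 0
    total_length_kb: float = 0.0
    avg_distance_kb: float = field(default=float("nan"))


def summarize_panel(panel: pd.DataFrame, genome_layout: pd.DataFrame,
                    gap_bins_kb: tuple = DEFAULT_GAP_BINS_KB) -> PanelSummary:
    """Compute the density table, subgenome/region shares and gap histogram.

    ``genome_layout`` has columns chrom, length_bp, subgenome.  Average
    distance per chromosome is chromosome length / marker count, reported in
    Kb at one decimal; shares are percentages at two decimals.
    """
    layout = genome_layout.set_index("chrom")
    bad = set(panel["chrom"].unique()) - set(layout.index)
    if bad:
        raise ValueError(f"panel markers on chromosome {sorted(bad)[0]!r} not in genome layout")

    counts = panel.groupby("chrom").size()
    per_rows = []
    gaps_kb_all = []
    for chrom in layout.index:
        n = int(counts.get(chrom, 0))
        length_kb = layout.at[chrom, "length_bp"] / 1000.0
        sub = panel[panel["chrom"] == chrom].sort_values("pos")
        gaps = np.diff(sub["pos"].to_numpy(float)) / 1000.0
        gaps_kb_all.append(gaps)
        per_rows.append({
            "chrom": chrom,
            "n_snps": n,
            "length_kb": round(length_kb, 2),
            "avg_distance_kb": average_spacing_kb(n, length_kb),
            "largest_gap_kb": round(float(gaps.max()), 1) if len(gaps) else float("nan"),
        })
    per_chromosome = pd.DataFrame(per_rows)

    n_total = int(per_chromosome["n_snps"].sum())
    total_length_kb = float((layout["length_bp"] / 1000.0).sum())

    sub_rows = []
    for sg, sub_layout in layout.groupby("subgenome"):
        n = int(counts.reindex(sub_layout.index).fillna(0).sum())
        length_kb = float(sub_layout["length_bp"].sum() / 1000.0)
        sub_rows.append({
            "subgenome": sg, "n_snps": n, "length_kb": round(length_kb, 2),
            "avg_distance_kb": average_spacing_kb(n, length_kb),
            "share_pct": share_percent(n, n_total),
        })
    subgenomes = pd.DataFrame(sub_rows)

    gaps = np.concatenate(gaps_kb_all) if gaps_kb_all else np.zeros(0)
    edges = np.asarray(gap_bins_kb, dtype=float)
    hist, _ = np.histogram(gaps, bins=edges)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"<{hi:g}" if lo == 0 else (f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}"))
    gap_histogram = pd.DataFrame({
        "bin_kb": labels, "count": hist,
        "share_pct": [share_percent(c, hist.sum()) for c in hist],
    })

    if "region_class" in panel.columns:
        rc = panel["region_class"].value_counts()
        regions = pd.DataFrame({
            "region_class": rc.index, "count": rc.values,
            "share_pct": [share_percent(c, n_total) for c in rc.values],
        })
        genic = panel[panel["region_class"] == "genic"]
        fc = genic["feature"].value_counts()
        features = pd.DataFrame({
            "feature": fc.index, "count": fc.values,
            "share_pct": [share_percent(c, len(genic)) for c in fc.values],
        })
    else:
        regions = pd.DataFrame(columns=["region_class", "count", "share_pct"])
        features = pd.DataFrame(columns=["feature", "count", "share_pct"])

    return PanelSummary(
        per_chromosome=per_chromosome, subgenomes=subgenomes,
        gap_histogram=gap_histogram, regions=regions, features=features,
        n_total=n_total, total_length_kb=round(total_length_kb, 2),
        avg_distance_kb=average_spacing_kb(n_total, total_length_kb),
    )


def design_panel(candidates: pd.DataFrame, config: FilterConfig | None = None,
                 repeat_mask: pd.DataFrame | None = None,
                 neighbor_variants: pd.DataFrame | None = None,
                 features: pd.DataFrame | None = None,
                 mode: str = "max_count") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full design pipeline: annotate, hard filters, design-score rule, spacing.

    Returns the selected panel and the extended attrition report (cascade
    stages plus ``design_score`` and ``spacing`` rows).
    """
    config = config or FilterConfig()
    if features is not None:
        candidates = annotate_snp_context(candidates, features)
    elif "region_class" not in candidates.columns:
        candidates = candidates.assign(region_class="intergenic", feature="none")
    survivors, report = apply_hard_filters(candidates, config, repeat_mask, neighbor_variants)
    scored = apply_design_score_rule(survivors, config)
    report.loc[len(report)] = ["design_score", len(survivors),
                               len(survivors) - len(scored), len(scored)]
    panel = select_spaced_markers(scored, config.min_gap_bp, mode=mode)
    report.loc[len(report)] = ["spacing", len(scored), len(scored) - len(panel), len(panel)]
    return panel, report
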