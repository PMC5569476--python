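"""Q+K mixed-linear-model association scan and candidate-region extraction.

The model for a trait vector y is

    y = mu + Q v + x beta + u + e,   u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with Q structure covariates (principal components by default, or an external
matrix), K a VanRaden genomic relationship matrix and x the tested marker's
alt-allele dosage.  Variance components are estimated once by REML on the
marker-free null model via the spectral decomposition of K and reused for
every marker (P3D); per-marker REML is available behind a flag.  Each marker
gets a Wald t-test on beta from the generalized least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .popgen import pca_coordinates


# ---------------------------------------------------------------------------
# kinship and structure
# ---------------------------------------------------------------------------

def kinship_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    K = Z Z' / (2 * sum p_i (1 - p_i)) with Z the per-marker-centered dosage
    matrix (missing dosages mean-imputed).  Positive semidefinite by
    construction (Gram matrix).
    """
    X = gm.dosage().values.T.astype(float)  # samples x markers
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers for kinship")
    X = X[:, poly]
    p = p[poly]
    idx = np.where(np.isnan(X))
    X[idx] = 2.0 * p[idx[1]]
    Z = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = Z @ Z.T / denom
    return pd.DataFrame(K, index=gm.samples, columns=gm.samples)


def structure_covariates(gm: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Structure covariates: intercept plus the top (k-1) principal components.

    Admixture proportions for k ancestral populations sum to one and span k-1
    dimensions, so k-1 PCs take their place as fixed effects.  ``k < 2``
    yields the intercept only.
    """
    n = gm.shape[1]
    out = pd.DataFrame({"intercept": np.ones(n)}, index=gm.samples)
    if k >= 2:
        pca = pca_coordinates(gm, n_components=k - 1)
        for c in pca.coordinates.columns:
            out[c] = pca.coordinates[c]
    return out


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _reml_neg_loglik(log_delta: float, yt: np.ndarray, Xt: np.ndarray,
                     d: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over sigma_g^2.

    Parameterization: V = sigma_g^2 (K + delta I); ``d`` are the eigenvalues
    of K and yt/Xt the eigen-rotated responses/design.
    """
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    n, p = Xt.shape
    XtWX = (Xt * w[:, None]).T @ Xt
    XtWy = (Xt * w[:, None]).T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yt - Xt @ beta
    rss = float(resid @ (w * resid))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(d + delta))
                 + logdet_XtWX + (n - p))
    return -ll


def _fit_reml_delta(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray,
                    grid: int = 61) -> float:
    """Profile-REML estimate of delta = sigma_e^2 / sigma_g^2 (coarse grid +
    bounded Brent refinement; deterministic)."""
    lo, hi = -12.0, 12.0
    logs = np.linspace(lo, hi, grid)
    vals = [_reml_neg_loglik(x, yt, Xt, d) for x in logs]
    i = int(np.argmin(vals))
    a = logs[max(i - 1, 0)]
    b = logs[min(i + 1, grid - 1)]
    res = optimize.minimize_scalar(_reml_neg_loglik, bounds=(a, b),
                                   args=(yt, Xt, d), method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.exp(res.x))


@dataclass
class MlmFit:
    """Null-model variance components shared across markers (P3D)."""

    delta: float
    sigma_g2: float
    sigma_e2: float
    eigvals: np.ndarray
    eigvecs: np.ndarray


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # find the offending columns by incremental rank
        collinear = []
        cols: list[int] = []
        for j, name in enumerate(X.columns):
            trial = X.values[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(str(name))
            else:
                cols.append(j)
        raise ValueError(f"singular fixed-effect design; collinear columns: {collinear}")


def fit_null_model(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> MlmFit:
    """REML variance components of y = X b + u + e with u ~ N(0, sigma_g^2 K)."""
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X
    delta = _fit_reml_delta(yt, Xt, d)
    w = 1.0 / (d + delta)
    XtWX = (Xt * w[:, None]).T @ Xt
    beta = np.linalg.solve(XtWX, (Xt * w[:, None]).T @ yt)
    resid = yt - Xt @ beta
    sigma_g2 = float(resid @ (w * resid)) / (len(y) - X.shape[1])
    return MlmFit(delta=delta, sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta,
                  eigvals=d, eigvecs=U)


def mlm_association(
    phenotype: pd.Series,
    gm: GenotypeMatrix,
    Q: pd.DataFrame | None = None,
    K: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    exact_reml: bool = False,
    loco: bool = False,
    min_samples: int = 30,
) -> pd.DataFrame:
    """Q+K mixed-model association scan.

    Parameters
    ----------
    phenotype
        Sample-indexed trait values; samples missing the trait are dropped.
    Q
        Structure covariates including an intercept column; default is an
        intercept only.  Supply :func:`structure_covariates` output (or an
        external matrix) for the Q+K model.
    K
        Kinship; default :func:`kinship_matrix` of the scan genotypes.
    maf_min
        Markers at or below this MAF are excluded before testing.
    exact_reml
        Re-estimate variance components per marker instead of reusing the
        null-model fit (P3D, the default).
    loco
        Leave-one-chromosome-out kinship: markers on a chromosome are tested
        against a K built from all other chromosomes, avoiding proximal
        contamination (the tested marker's own signal being absorbed into the
        polygenic term).  Requires ``positions``; ignores an explicit ``K``.

    Returns
    -------
    DataFrame with effect (alt-allele), se, p_value, neglog10_p, maf and
    (when ``positions`` is given) chrom/pos per tested marker.
    """
    pheno = phenotype.dropna()
    samples = [s for s in gm.samples if s in pheno.index]
    if len(samples) < min_samples:
        raise ValueError(f"need >= {min_samples} phenotyped samples, have {len(samples)}")
    sub = gm.subset(samples=samples)
    y = pheno.loc[samples].to_numpy(float)

    maf = sub.maf()
    keep = maf[maf > maf_min].index
    dos = sub.subset(markers=keep).dosage().values.T.astype(float)  # samples x markers
    col_mean = np.nanmean(dos, axis=0)
    idx = np.where(np.isnan(dos))
    dos[idx] = col_mean[idx[1]]

    if Q is None:
        Xdf = pd.DataFrame({"intercept": np.ones(len(samples))}, index=samples)
    else:
        Xdf = Q.loc[samples].copy()
        if not np.allclose(Xdf.iloc[:, 0], 1.0):
            Xdf.insert(0, "intercept", 1.0)
    _check_design(Xdf)
    X = Xdf.to_numpy(float)

    n = len(samples)
    p = X.shape[1]
    dfree = n - p - 1
    effects = np.full(dos.shape[1], np.nan)
    ses = np.full(dos.shape[1], np.nan)
    pvals = np.full(dos.shape[1], np.nan)

    # (marker columns, kinship) contexts: one global K, or one per
    # left-out chromosome under LOCO
    if loco:
        if positions is None:
            raise ValueError("loco=True requires marker positions")
        chrom = positions.loc[keep, "chrom"].to_numpy()
        contexts = []
        for c in pd.unique(chrom):
            cols = np.where(chrom == c)[0]
            rest = keep[chrom != c]
            if len(rest) == 0:
                raise ValueError(f"LOCO leaves no markers to build K without {c}")
            contexts.append((cols, kinship_matrix(sub.subset(markers=rest)).values))
    else:
        if K is None:
            Km = kinship_matrix(sub).values
        else:
            Km = K.loc[samples, samples].to_numpy(float)
        contexts = [(np.arange(dos.shape[1]), Km)]

    def _scan_with_delta(delta, d, yt, Xt, Gt, cols):
        w = 1.0 / (d + delta)
        XtW = Xt * w[:, None]
        Ainv = np.linalg.inv(XtW.T @ Xt)
        # residualize y and each marker against X in the W metric
        by = Ainv @ (XtW.T @ yt)
        ry = yt - Xt @ by
        B = Ainv @ (XtW.T @ Gt)
        rG = Gt - Xt @ B
        gWg = np.einsum("ij,i,ij->j", rG, w, rG)
        gWy = np.einsum("ij,i,i->j", rG, w, ry)
        yWy = float(ry @ (w * ry))
        ok = gWg > 1e-12
        beta = np.where(ok, gWy / np.where(ok, gWg, 1.0), np.nan)
        rss = yWy - beta ** 2 * gWg
        sigma2 = rss / dfree
        se = np.sqrt(np.where(ok, sigma2 / np.where(ok, gWg, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        pv = 2.0 * stats.t.sf(np.abs(t), dfree)
        effects[cols] = np.where(ok, beta, np.nan)
        ses[cols] = se
        pvals[cols] = np.where(ok, np.maximum(pv, np.finfo(float).tiny), np.nan)

    for cols, Km in contexts:
        null = fit_null_model(y, X, Km)
        U, d = null.eigvecs, null.eigvals
        yt = U.T @ y
        Xt = U.T @ X
        Gt = U.T @ dos[:, cols]
        if exact_reml:
            for jj, j in enumerate(cols):
                Xj = np.column_stack([Xt, Gt[:, jj]])
                delta_j = _fit_reml_delta(yt, Xj, d)
                _scan_with_delta(delta_j, d, yt, Xt, Gt[:, [jj]], np.array([j]))
        else:
            _scan_with_delta(null.delta, d, yt, Xt, Gt, cols)

    out = pd.DataFrame({
        "maf": maf.loc[keep].to_numpy(float),
        "effect": effects,
        "se": ses,
        "p_value": pvals,
    }, index=keep)
    out["neglog10_p"] = -np.log10(out["p_value"])
    if positions is not None:
        out["chrom"] = positions.loc[keep, "chrom"].to_numpy()
        out["pos"] = positions.loc[keep, "pos"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# thresholds and candidate regions
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def significance_thresholds(n_markers: int,
                            fixed_threshold: float = 1e-5) -> tuple[float, float]:
    """(Bonferroni 1/n at two significant figures, fixed reporting threshold)."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return _round_sig(1.0 / n_markers, 2), fixed_threshold


@dataclass
class RegionSet:
    """Merged candidate regions around significant SNPs, with member genes."""

    regions: pd.DataFrame       # chrom, start, end, start_mb, end_mb, n_snps, snps
    genes: pd.DataFrame         # region index, gene_id, chrom, start, end


def peak_regions_and_genes(
    results: pd.DataFrame,
    threshold: float = 1e-5,
    window_bp: int = 500_000,
    gene_annotation: pd.DataFrame | None = None,
    chromosome_lengths: pd.Series | None = None,
) -> RegionSet:
    """Expand significant SNPs by ±window_bp and merge overlapping intervals.

    ``results`` needs chrom, pos and p_value columns.  Region bounds are
    clipped to [1, chromosome length] when lengths are supplied, and reported
    in Mb at two decimals.  Genes whose spans intersect a region are listed
    with it; an annotation chromosome absent from the results is only a
    warning.
    """
    sig = results[results["p_value"] < threshold]
    region_rows = []
    gene_rows = []
    for chrom, sub in sig.groupby("chrom"):
        sub = sub.sort_values("pos")
        intervals: list[list] = []
        for marker, row in sub.iterrows():
            s = max(1, int(row["pos"]) - window_bp)
            e = int(row["pos"]) + window_bp
            if chromosome_lengths is not None and chrom in chromosome_lengths.index:
                e = min(e, int(chromosome_lengths[chrom]))
            if intervals and s <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], e)
                intervals[-1][2].append(marker)
            else:
                intervals.append([s, e, [marker]])
        for s, e, members in intervals:
            region_rows.append({
                "chrom": chrom, "start": s, "end": e,
                "start_mb": round(s / 1e6, 2), "end_mb": round(e / 1e6, 2),
                "n_snps": len(members), "snps": ",".join(map(str, members)),
            })
    regions = pd.DataFrame(region_rows,
                           columns=["chrom", "start", "end", "start_mb",
                                    "end_mb", "n_snps", "snps"])
    if gene_annotation is not None and len(regions):
        genes = gene_annotation[gene_annotation["ftype"] == "gene"] \
            if "ftype" in gene_annotation.columns else gene_annotation
        known = set(genes["chrom"].unique())
        for ridx, r in regions.iterrows():
            if r["chrom"] not in known:
                warnings.warn(f"no gene annotation for chromosome {r['chrom']}")
                continue
            hit = genes[(genes["chrom"] == r["chrom"])
                        & (genes["end"] >= r["start"]) & (genes["start"] <= r["end"])]
            for _, g in hit.iterrows():
                gene_rows.append({"region": ridx, "gene_id": g["gene_id"],
                                  "chrom": g["chrom"], "start": g["start"],
                                  "end": g["end"]})
    genes_df = pd.DataFrame(gene_rows, columns=["region", "gene_id", "chrom",
                                                "start", "end"])
    return RegionSet(regions=regions, genes=genes_df)
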