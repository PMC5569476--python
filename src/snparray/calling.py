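"""Genotype calling from two-channel array intensities on a polyploid background.

Each marker's samples live in (theta, NormR) space: theta is the normalized
allele-contrast angle (0 = one homozygote, 1 = the other) and NormR the total
signal.  Genotype classes separate along theta, so the caller fits a 1-D
Gaussian mixture on theta (k chosen by BIC, up to five components for an
allotetraploid locus where homeologous copies create AAAA..BBBB ladders) and
uses NormR only to gate no-signal (NG) samples out of fitting and calling.

The adjustment step mirrors the manual curation used on polyploid array data:
adjacent clusters closer than a delta are merged (e.g. AAAA with AAAB, ABBB
with BBBB), and a locus still holding more than three clusters is collapsed to
three by merging its closest off-center pairs, so that every called sample
receives a diploidized AA/AB/BB label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .genotypes import GenotypeMatrix

TETRA_LABELS = ("AAAA", "AAAB", "AABB", "ABBB", "BBBB")
TETRA_ANCHORS = (0.05, 0.275, 0.5, 0.725, 0.95)
DIPLOID_LABELS = ("AA", "AB", "BB")
DIPLOID_ANCHORS = (0.0, 0.5, 1.0)

PATTERNS = ("monomorphic", "two_cluster", "three_cluster",
            "partial_ng", "failed", "polyploid_adjusted")


@dataclass(frozen=True)
class CallingConfig:
    """Caller thresholds.

    ``merge_delta_theta`` merges adjacent clusters closer than this along
    theta (sub-cluster artifacts; the canonical five-class ladder is spaced
    ~0.23 apart and survives).  ``ng_r_min`` is the NormR floor below which a
    sample has no usable signal (NG).  ``assign_max_distance`` is the
    standardized-theta radius beyond which a sample is off-cluster and left
    uncalled; ``min_assign_sd`` floors the cluster sd used for that
    standardization so that near-noise-free clusters keep a finite capture
    radius.
    """

    max_clusters: int = 5
    merge_delta_theta: float = 0.15
    ng_r_min: float = 0.2
    assign_max_distance: float = 4.0
    min_cluster_weight: float = 0.02
    min_assign_sd: float = 0.02
    seed: int = 17

    def __post_init__(self):
        if not (1 <= self.max_clusters <= 5):
            raise ValueError("max_clusters must be in 1..5")
        for name in ("merge_delta_theta", "ng_r_min", "assign_max_distance",
                     "min_cluster_weight", "min_assign_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class IntensityMatrix:
    """Per-(marker, sample) theta and NormR matrices (markers x samples)."""

    theta: pd.DataFrame
    norm_r: pd.DataFrame

    def __post_init__(self):
        if not self.theta.index.equals(self.norm_r.index) or \
           not self.theta.columns.equals(self.norm_r.columns):
            raise ValueError("theta and norm_r must share markers and samples")
        t = self.theta.values
        if np.nanmin(t) < 0 or np.nanmax(t) > 1:
            raise ValueError("theta outside [0, 1]")
        if np.nanmin(self.norm_r.values) < 0:
            raise ValueError("norm_r must be non-negative")

    @property
    def markers(self) -> pd.Index:
        return self.theta.index

    @property
    def samples(self) -> pd.Index:
        return self.theta.columns


@dataclass
class ClusterModel:
    """Fitted (and possibly adjusted) theta-cluster structure of one marker."""

    marker: str
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    labels: tuple[str, ...] = ()        # diploidized AA/AB/BB per cluster
    tetra_labels: tuple[str, ...] = ()  # AAAA..BBBB per cluster
    bic: float = float("nan")
    failed: bool = False
    merged: bool = False
    polyploid_complex: bool = False

    @property
    def k(self) -> int:
        return 0 if self.failed else len(self.means)


def _monotone_assign(means: np.ndarray, anchors: np.ndarray) -> list[int]:
    """Min-cost strictly-increasing assignment of sorted means to anchors."""
    k, m = len(means), len(anchors)
    cost = np.abs(means[:, None] - anchors[None, :])
    INF = float("inf")
    dp = np.full((k + 1, m + 1), INF)
    dp[0, :] = 0.0
    choice = np.zeros((k + 1, m + 1), dtype=int)
    for i in range(1, k + 1):
        for j in range(1, m + 1):
            skip = dp[i, j - 1]
            take = dp[i - 1, j - 1] + cost[i - 1, j - 1]
            if take <= skip:
                dp[i, j] = take
                choice[i, j] = 1
            else:
                dp[i, j] = skip
                choice[i, j] = 0
    out = []
    i, j = k, m
    while i > 0:
        if choice[i, j]:
            out.append(j - 1)
            i -= 1
        j -= 1
    return out[::-1]


def _label_clusters(model: ClusterModel) -> ClusterModel:
    means = np.asarray(model.means, dtype=float)
    if 0 < len(means) <= 5:
        tetra = _monotone_assign(means, np.array(TETRA_ANCHORS))
        tetra_labels = tuple(TETRA_LABELS[i] for i in tetra)
    else:
        tetra_labels = ()
    if len(means) <= 3:
        dip = _monotone_assign(means, np.array(DIPLOID_ANCHORS))
        labels = tuple(DIPLOID_LABELS[i] for i in dip)
    else:
        labels = ()
    return replace(model, labels=labels, tetra_labels=tetra_labels)


def fit_theta_clusters(theta: np.ndarray, norm_r: np.ndarray,
                       config: CallingConfig | None = None,
                       marker: str = "") -> ClusterModel:
    """Fit a 1-D Gaussian mixture on theta; k in 1..max_clusters by min BIC.

    Samples with NormR below ``ng_r_min`` are excluded from fitting.  Fewer
    than two usable samples flags the marker failed.  Clusters lighter than
    ``min_cluster_weight`` are dropped by refitting with one fewer component.
    """
    config = config or CallingConfig()
    theta = np.asarray(theta, dtype=float)
    norm_r = np.asarray(norm_r, dtype=float)
    usable = (norm_r >= config.ng_r_min) & ~np.isnan(theta)
    x = theta[usable].reshape(-1, 1)
    if len(x) < 2:
        return ClusterModel(marker=marker, means=np.zeros(0), sds=np.zeros(0),
                            weights=np.zeros(0), failed=True)

    def _fit(k: int) -> GaussianMixture:
        # k-means initialization separates spike-like classes even when one
        # genotype dominates (quantile seeds would then collide)
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             init_params="k-means++", n_init=3,
                             random_state=config.seed, reg_covar=1e-6)
        gm.fit(x)
        return gm

    kmax = min(config.max_clusters, len(np.unique(x[:, 0])), len(x))
    fits = {k: _fit(k) for k in range(1, kmax + 1)}
    best_k = min(fits, key=lambda k: fits[k].bic(x))
    gm = fits[best_k]
    while best_k > 1 and gm.weights_.min() < config.min_cluster_weight:
        best_k -= 1
        gm = fits[best_k]

    order = np.argsort(gm.means_[:, 0])
    model = ClusterModel(
        marker=marker,
        means=gm.means_[order, 0].copy(),
        sds=np.sqrt(gm.covariances_[order, 0]),
        weights=gm.weights_[order].copy(),
        bic=float(gm.bic(x)),
    )
    return _label_clusters(model)


def _merge_pair(model: ClusterModel, i: int) -> ClusterModel:
    """Merge clusters i and i+1 into their weight-averaged Gaussian."""
    w = model.weights
    m = model.means
    s = model.sds
    wt = w[i] + w[i + 1]
    mean = (w[i] * m[i] + w[i + 1] * m[i + 1]) / wt
    # second moment of the two-component mixture
    var = (w[i] * (s[i] ** 2 + m[i] ** 2) + w[i + 1] * (s[i + 1] ** 2 + m[i + 1] ** 2)) / wt \
        - mean ** 2
    means = np.delete(m, i + 1); means[i] = mean
    sds = np.delete(s, i + 1); sds[i] = np.sqrt(max(var, 0.0))
    weights = np.delete(w, i + 1); weights[i] = wt
    return replace(model, means=means, sds=sds, weights=weights, merged=True)


def adjust_clusters(model: ClusterModel,
                    config: CallingConfig | None = None) -> ClusterModel:
    """Polyploid cluster adjustment: threshold merging then diploidized labels.

    Adjacent clusters with mean-theta gap below ``merge_delta_theta`` are
    merged (closest pair first) until none qualify.  A model still holding
    more than three clusters is a true polyploid ladder: it is flagged
    ``polyploid_complex`` and collapsed to three clusters by merging its
    closest adjacent pairs, preferring off-center pairs on ties so that the
    homozygote-side ladder classes (AAAA/AAAB, ABBB/BBBB) coalesce first.
    Idempotent: re-adjusting an adjusted model changes nothing.
    """
    config = config or CallingConfig()
    if model.failed or model.k <= 1:
        return _label_clusters(model)
    out = model
    while out.k > 1:
        gaps = np.diff(out.means)
        i = int(np.argmin(gaps))
        if gaps[i] >= config.merge_delta_theta:
            break
        out = _merge_pair(out, i)
    if out.k > 3:
        out = replace(out, polyploid_complex=True)
        while out.k > 3:
            gaps = np.diff(out.means)
            mids = (out.means[:-1] + out.means[1:]) / 2.0
            # smallest gap; ties broken toward the pair farthest from theta 0.5
            order = sorted(range(len(gaps)),
                           key=lambda j: (round(gaps[j], 12), -abs(mids[j] - 0.5), j))
            out = _merge_pair(out, order[0])
    return _label_clusters(out)


def call_genotypes(model: ClusterModel, theta: np.ndarray, norm_r: np.ndarray,
                   config: CallingConfig | None = None) -> np.ndarray:
    """Per-sample diploidized calls for one marker.

    Failed marker: ``--`` for every sample.  NormR below ``ng_r_min``: NG.
    Otherwise the nearest cluster's label, unless the standardized theta
    distance to every cluster exceeds ``assign_max_distance`` (off-cluster,
    left as ``--``).
    """
    config = config or CallingConfig()
    theta = np.asarray(theta, dtype=float)
    norm_r = np.asarray(norm_r, dtype=float)
    n = len(theta)
    calls = np.full(n, "--", dtype=object)
    if model.failed or not model.labels:
        return calls
    ng = (norm_r < config.ng_r_min) | np.isnan(theta)
    calls[ng] = "NG"
    ok = ~ng
    if ok.any():
        sds = np.maximum(model.sds, config.min_assign_sd)
        z = np.abs(theta[ok, None] - model.means[None, :]) / sds[None, :]
        nearest = np.argmin(z, axis=1)
        zmin = z[np.arange(len(nearest)), nearest]
        labels = np.array(model.labels, dtype=object)[nearest]
        labels[zmin > config.assign_max_distance] = "--"
        calls[ok] = labels
    return calls


def classify_locus_pattern(model: ClusterModel, calls: np.ndarray) -> str:
    """Locus pattern taxonomy: failed, polyploid_adjusted, partial_ng, or by k."""
    calls = np.asarray(calls, dtype=object)
    if model.failed or (len(calls) and (calls == "--").all()):
        return "failed"
    if model.merged or model.polyploid_complex:
        return "polyploid_adjusted"
    if (calls == "NG").any():
        return "partial_ng"
    if model.k == 1:
        return "monomorphic"
    if model.k == 2:
        return "two_cluster"
    return "three_cluster"


def call_dataset(
    intensities: IntensityMatrix,
    config: CallingConfig | None = None,
) -> tuple[GenotypeMatrix, dict[str, ClusterModel], pd.Series]:
    """Fit, adjust and call every marker of an intensity matrix.

    Returns the genotype matrix, the adjusted per-marker cluster models and
    the per-marker pattern classification.
    """
    config = config or CallingConfig()
    calls = {}
    models: dict[str, ClusterModel] = {}
    patterns = {}
    for marker in intensities.markers:
        th = intensities.theta.loc[marker].to_numpy(float)
        r = intensities.norm_r.loc[marker].to_numpy(float)
        model = adjust_clusters(fit_theta_clusters(th, r, config, marker=str(marker)), config)
        c = call_genotypes(model, th, r, config)
        calls[marker] = c
        models[str(marker)] = model
        patterns[marker] = classify_locus_pattern(model, c)
    call_df = pd.DataFrame.from_dict(calls, orient="index", columns=intensities.samples)
    call_df = call_df.loc[intensities.markers]
    return GenotypeMatrix(call_df), models, pd.Series(patterns).loc[intensities.markers]
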