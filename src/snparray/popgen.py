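"""Population-level analyses: 1-IBS distances, neighbor joining, PCA and LD.

IBS between two samples at one locus is the shared-allele fraction of their
diploidized genotypes (AA vs AA -> 1, AA vs AB -> 0.5, AA vs BB -> 0); the
pairwise distance is one minus the mean IBS over co-called loci.  Neighbor
joining follows Saitou & Nei's Q-criterion with a deterministic lexicographic
tie-break.  LD is measured as the composite (dosage-correlation) r² — phase is
unknown in array data — with D' from EM-estimated haplotype frequencies.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo

from .genotypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over samples."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix has a non-zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def ibs_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean identity-by-state over co-called loci, for every sample pair."""
    if gm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = gm.dosage().values  # markers x samples
    n = d.shape[1]
    ids = list(map(str, gm.samples))
    out = np.zeros((n, n))
    for i in range(n):
        di = d[:, i]
        for j in range(i + 1, n):
            dj = d[:, j]
            both = ~np.isnan(di) & ~np.isnan(dj)
            if not both.any():
                raise ValueError(f"no co-called loci for pair ({ids[i]}, {ids[j]})")
            ibs = 1.0 - np.abs(di[both] - dj[both]) / 2.0
            out[i, j] = out[j, i] = 1.0 - ibs.mean()
    return DistanceMatrix(ids=ids, values=out)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str, children=None):
        self.name = name
        self.children = children or []  # list of (node, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        parts = [f"{c.newick()}:{bl:.10g}" for c, bl in self.children]
        return "(" + ",".join(parts) + ")"


@dataclass
class PhylogeneticTree:
    """Unrooted tree over samples, kept as a Newick string plus a leaf metric."""

    newick: str
    _root: _Node | None = field(default=None, repr=False)

    def to_biopython(self):
        """Parse into a Bio.Phylo tree."""
        return Phylo.read(_io.StringIO(self.newick), "newick")

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length metric between all leaf pairs."""
        tree = self.to_biopython()
        leaves = tree.get_terminals()
        names = [l.name for l in leaves]
        depths = {}
        # distance via lowest common ancestor using Bio.Phylo trace
        n = len(leaves)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = tree.distance(leaves[i], leaves[j])
                out[i, j] = out[j, i] = d
        return pd.DataFrame(out, index=names, columns=names)


def neighbor_joining_tree(dist: DistanceMatrix) -> PhylogeneticTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined at each step; exact ties
    break by the lexicographically smallest (name, name) pair.  A negative
    branch length is clamped to zero with the deficit moved to the sibling
    edge, preserving the joined pair's mutual distance.
    """
    names = [str(x) for x in dist.ids]
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [_Node(nm) for nm in names]
    labels = list(names)
    D = dist.values.astype(float).copy()

    if n == 2:
        root = _Node("", [(nodes[0], D[0, 1] / 2), (nodes[1], D[0, 1] / 2)])
        return PhylogeneticTree(newick=root.newick() + ";", _root=root)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, k=1)
        qvals = Q[iu, ju]
        qmin = qvals.min()
        cand = [(tuple(sorted((labels[i], labels[j]))), i, j)
                for i, j in zip(iu[qvals == qmin], ju[qvals == qmin])]
        _, i, j = min(cand)
        dij = D[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        new = _Node("", [(nodes[i], li), (nodes[j], lj)])
        new_label = min(labels[i], labels[j])
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [new_label]
        D = D2

    # closed-form star join of the final three nodes
    (a, b, c) = (0, 1, 2)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = D[a, b] - la
    lc = D[a, c] - la
    lens = np.array([la, lb, lc])
    lens[lens < 0] = 0.0
    root = _Node("", list(zip(nodes, lens)))
    return PhylogeneticTree(newick=root.newick() + ";", _root=root)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coordinates: pd.DataFrame        # samples x components
    eigenvalues: np.ndarray
    variance_explained: np.ndarray   # fraction per kept component


def pca_coordinates(gm: GenotypeMatrix, n_components: int = 10,
                    scale: bool = False) -> PcaResult:
    """PCA of the samples x markers dosage matrix.

    Dosages are mean-imputed per marker and mean-centered; ``scale`` divides
    by the per-marker standard deviation.  Components carry a deterministic
    sign (largest-magnitude sample coordinate positive).
    """
    X = gm.dosage().values.T.astype(float)  # samples x markers
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    col_mean = np.nanmean(X, axis=0)
    poly = np.nanstd(X, axis=0) > 0
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    X = X[:, poly]
    col_mean = col_mean[poly]
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2 / (n - 1)
    k = min(n_components, len(s))
    coords = U[:, :k] * s[:k]
    # deterministic sign: largest |coordinate| positive per component
    for c in range(k):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    frac = eig[:k] / eig.sum()
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=gm.samples,
                                 columns=[f"PC{i+1}" for i in range(k)]),
        eigenvalues=eig[:k],
        variance_explained=frac,
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LdResult:
    pairs: pd.DataFrame        # marker_a, marker_b, chrom, dist_bp, r2, d_prime
    decay_curve: pd.DataFrame  # bin_mid_bp, mean_r2, smoothed_r2, n_pairs
    decay_distance_bp: float


def _em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray,
                        n_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """EM haplotype-frequency estimate from two unphased dosage vectors.

    Returns frequencies of the four haplotypes indexed ``2*a1 + a2`` where
    ``a1``/``a2`` are the alt-allele indicators at the two loci (0 = ref).
    Only the double-heterozygote genotype class is phase-ambiguous; everything
    else contributes known haplotype counts.
    """
    both = ~np.isnan(ga) & ~np.isnan(gb)
    a = ga[both].astype(int)
    b = gb[both].astype(int)
    if len(a) == 0:
        return np.full(4, np.nan)
    base = np.zeros(4)
    n_dh = 0
    for ai, bi in zip(a, b):
        if ai == 1 and bi == 1:
            n_dh += 1
        elif ai == 1:          # locus 1 het, locus 2 homozygous
            y = bi // 2
            base[y] += 1
            base[2 + y] += 1
        elif bi == 1:          # locus 2 het, locus 1 homozygous
            x = ai // 2
            base[2 * x] += 1
            base[2 * x + 1] += 1
        else:                  # both homozygous
            base[2 * (ai // 2) + (bi // 2)] += 2
    p1, p2 = a.mean() / 2.0, b.mean() / 2.0  # alt-allele frequencies
    p = np.array([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2])
    p = np.maximum(p, 1e-9)
    p /= p.sum()
    for _ in range(n_iter):
        counts = base.copy()
        if n_dh:
            cis = p[0] * p[3]     # ref-ref / alt-alt phase
            trans = p[1] * p[2]   # ref-alt / alt-ref phase
            w = 0.5 if cis + trans == 0 else cis / (cis + trans)
            counts[[0, 3]] += n_dh * w
            counts[[1, 2]] += n_dh * (1 - w)
        p_new = counts / counts.sum()
        if np.abs(p_new - p).max() < tol:
            return p_new
        p = p_new
    return p


def d_prime(ga: np.ndarray, gb: np.ndarray) -> float:
    """Lewontin's D' from EM haplotype frequencies of two dosage vectors."""
    p = _em_haplotype_freqs(ga, gb)
    if np.isnan(p).any():
        return float("nan")
    pa = p[2] + p[3]  # alt frequency, locus 1
    pb = p[1] + p[3]  # alt frequency, locus 2
    D = p[3] - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return float("nan")
    return float(min(abs(D) / dmax, 1.0))


def r_squared(ga: np.ndarray, gb: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosages (pairwise-complete)."""
    both = ~np.isnan(ga) & ~np.isnan(gb)
    a, b = ga[both], gb[both]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_statistics(gm: GenotypeMatrix, positions: pd.DataFrame,
                  max_dist: int = 1_000_000, bin_width: int = 10_000,
                  smooth_window: int = 3,
                  compute_d_prime: bool = True) -> LdResult:
    """Pairwise r² (and D') for same-chromosome marker pairs within max_dist,
    the binned decay curve, and the half-maximum decay distance.

    The decay distance is the smallest bin midpoint at which the (rolling-mean
    smoothed) binned mean r² falls to half of its maximum; NaN if the curve
    never decays that far.  Monomorphic markers are skipped pair-wise.
    """
    dos = gm.dosage()
    pos = positions.loc[gm.markers]
    rows = []
    for chrom, sub in pos.groupby("chrom"):
        sub = sub.sort_values("pos")
        ids = list(sub.index)
        p = sub["pos"].to_numpy(float)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                dist = p[j] - p[i]
                if dist > max_dist:
                    break
                ga = dos.loc[ids[i]].to_numpy(float)
                gb = dos.loc[ids[j]].to_numpy(float)
                r2 = r_squared(ga, gb)
                if np.isnan(r2):
                    continue  # monomorphic or unmeasurable pair
                dp = d_prime(ga, gb) if compute_d_prime else float("nan")
                rows.append({"marker_a": ids[i], "marker_b": ids[j],
                             "chrom": chrom, "dist_bp": dist,
                             "r2": r2, "d_prime": dp})
    pairs = pd.DataFrame(rows, columns=["marker_a", "marker_b", "chrom",
                                        "dist_bp", "r2", "d_prime"])

    edges = np.arange(0, max_dist + bin_width, bin_width)
    mids = (edges[:-1] + edges[1:]) / 2.0
    mean_r2 = np.full(len(mids), np.nan)
    counts = np.zeros(len(mids), dtype=int)
    if len(pairs):
        dist = pairs["dist_bp"].to_numpy(float)
        r2v = pairs["r2"].to_numpy(float)
        which = np.clip(np.digitize(dist, edges) - 1, 0, len(mids) - 1)
        for b in range(len(mids)):
            sel = which == b
            counts[b] = int(sel.sum())
            if counts[b]:
                mean_r2[b] = float(r2v[sel].mean())
    smoothed = pd.Series(mean_r2).rolling(smooth_window, center=True,
                                          min_periods=1).mean().to_numpy()
    curve = pd.DataFrame({"bin_mid_bp": mids, "mean_r2": mean_r2,
                          "smoothed_r2": smoothed, "n_pairs": counts})

    # half-maximum crossing; +inf when LD has not decayed that far within
    # max_dist, NaN when there is no curve at all
    decay = float("nan")
    valid = ~np.isnan(smoothed)
    if valid.any():
        half = np.nanmax(smoothed) / 2.0
        below = np.where(valid & (smoothed <= half))[0]
        decay = float(mids[below[0]]) if len(below) else float("inf")
    return LdResult(pairs=pairs, decay_curve=curve, decay_distance_bp=decay)
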