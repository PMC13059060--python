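"""Cohort structure: genotype PCA, allele-sharing distances, neighbor
joining, and assignment of males to the weakly (M1) and strongly (M2)
differentiated Y-haplotype classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleSheet


@dataclass
class PcaResult:
    coordinates: np.ndarray  # samples x k
    variance_explained: np.ndarray  # k
    samples: list[str]


def _dosage_standardized(gm: GenotypeMatrix) -> np.ndarray:
    """Samples x loci dosage matrix, mean-imputed, centered, and scaled by
    sqrt(2 p (1-p)); monomorphic or fully-missing loci contribute zeros."""
    codes = gm.codes.astype(float).T  # samples x loci
    miss = codes < 0
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(miss, np.nan, codes).sum(axis=0) / (~miss).sum(axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    codes = np.where(miss, col_mean[None, :], codes)
    p = col_mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    z = np.zeros_like(codes)
    z[:, ok] = (codes[:, ok] - col_mean[None, ok]) / scale[None, ok]
    return z


def pca_genotypes(gm: GenotypeMatrix, k: int = 2) -> PcaResult:
    """PCA of standardized genotype dosages.

    Coordinates are the top-k left singular vectors scaled by their singular
    values; the sign of each component is fixed so that its
    largest-magnitude locus loading is positive.  If k exceeds the matrix
    rank the trailing components are zero.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    z = _dosage_standardized(gm)
    if not np.any(z != 0):
        raise ValueError("no polymorphic locus; PCA undefined")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    kk = min(k, rank)
    coords = np.zeros((gm.n_samples, k))
    var = np.zeros(k)
    total = float(np.sum(s**2))
    for j in range(kk):
        sign = np.sign(vt[j, np.argmax(np.abs(vt[j]))]) or 1.0
        coords[:, j] = sign * u[:, j] * s[j]
        var[j] = s[j] ** 2 / total
    return PcaResult(coordinates=coords, variance_explained=var, samples=list(gm.samples))


def ibs_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing distance matrix: 1 - shared alleles / (2 x co-called loci).

    Missing calls are excluded pairwise; a pair with no co-called locus is
    an error.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    codes = gm.codes
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[:, i] >= 0) & (codes[:, j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"samples {gm.samples[i]} and {gm.samples[j]} share no called locus"
                )
            diff = np.abs(codes[ok, i].astype(int) - codes[ok, j].astype(int)).sum()
            out[i, j] = out[j, i] = diff / (2.0 * m)
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(distances: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Ties in the Q-matrix are broken by the lowest (row, column) index pair
    in the current node order; negative branch lengths are clamped to 0
    with the deficit transferred to the sibling branch.
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    d = distances.to_numpy(dtype=float).copy()
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix has undefined entries")
    nodes = [str(l) for l in labels]

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_new = np.zeros((r - 1, r - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # final trifurcation via the three-point formulas
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    l0, l1, l2 = (max(v, 0.0) for v in (l0, l1, l2))
    return (
        f"({nodes[0]}:{_fmt(l0)},{nodes[1]}:{_fmt(l1)},{nodes[2]}:{_fmt(l2)});"
    )


def assign_male_classes(
    scores: pd.DataFrame, sheet: SampleSheet, thr: float = 0.6
) -> dict[str, str]:
    """Score rule: males with sex-linkage score >= ``thr`` are M2, others M1.

    ``scores`` is the output of :func:`slrscan.linkage.sample_scores` on an
    SLR panel.  With < 2 males every male is labelled "unknown", as is any
    male with an undefined score.
    """
    males = sheet.ids_of_sex("M")
    if len(males) < 2:
        return {m: "unknown" for m in males}
    by_id = dict(zip(scores["sample_id"], scores["score"]))
    out = {}
    for m in males:
        s = by_id.get(m, np.nan)
        out[m] = "unknown" if np.isnan(s) else ("M2" if s >= thr else "M1")
    return out


def _kmeans_1d_2(x: np.ndarray) -> np.ndarray:
    """Optimal 2-cluster split of a 1-D vector (exact, by sorted scan).

    Returns 0/1 labels; cluster 1 is the one with the larger mean.
    """
    order = np.argsort(x)
    xs = x[order]
    n = len(xs)
    cs = np.cumsum(xs)
    cs2 = np.cumsum(xs * xs)
    best_split, best_cost = 1, np.inf
    for m in range(1, n):
        s1, s2 = cs[m - 1], cs[-1] - cs[m - 1]
        q1, q2 = cs2[m - 1], cs2[-1] - cs2[m - 1]
        cost = (q1 - s1 * s1 / m) + (q2 - s2 * s2 / (n - m))
        if cost < best_cost - 1e-15:
            best_split, best_cost = m, cost
    labels = np.zeros(n, dtype=int)
    labels[order[best_split:]] = 1
    return labels


def assign_male_classes_pca(
    gm_slr: GenotypeMatrix, sheet: SampleSheet
) -> dict[str, str]:
    """PCA rule: 2-means on male PC1 coordinates of SLR SNPs; the cluster
    whose PC1 mean is nearer the female centroid is M1."""
    males = sheet.ids_of_sex("M")
    if len(males) < 2:
        return {m: "unknown" for m in males}
    res = pca_genotypes(gm_slr, k=1)
    pc1 = dict(zip(res.samples, res.coordinates[:, 0]))
    female_centroid = float(np.mean([pc1[s] for s in sheet.ids_of_sex("F")]))
    mx = np.array([pc1[m] for m in males])
    labels = _kmeans_1d_2(mx)
    means = [mx[labels == c].mean() for c in (0, 1)]
    m1_cluster = int(np.argmin([abs(mu - female_centroid) for mu in means]))
    return {m: ("M1" if labels[i] == m1_cluster else "M2") for i, m in enumerate(males)}
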