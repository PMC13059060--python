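"""Linkage disequilibrium from unphased genotypes.

r² is the squared Pearson correlation of alt-allele dosages over samples
called at both loci (composite LD).  This estimator needs no phasing, is
deterministic, and is invariant to REF/ALT relabelling of either locus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Region, SampleSheet


def dosage_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared dosage correlation for one locus pair, pairwise deletion.

    NaN when fewer than 2 samples are called at both loci or either locus is
    monomorphic among the co-called samples.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i >= 0) & (g_j >= 0)
    if ok.sum() < 2:
        return float("nan")
    x = g_i[ok].astype(float)
    y = g_j[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def pairwise_r2(codes: np.ndarray) -> np.ndarray:
    """Vectorized pairwise dosage r² for a loci x samples code block.

    Pairwise deletion of missing calls; entries with < 2 co-called samples
    or a monomorphic member are NaN.  Matches :func:`dosage_r2` entrywise.
    """
    x = np.asarray(codes, dtype=float)
    called = x >= 0
    x0 = np.where(called, x, 0.0)
    m = called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = m @ m.T
        sx = x0 @ m.T
        sy = m @ x0.T
        sxy = x0 @ x0.T
        sxx = (x0 * x0) @ m.T
        syy = m @ (x0 * x0).T
        mx = sx / n
        my = sy / n
        cov = sxy / n - mx * my
        vx = sxx / n - mx * mx
        vy = syy / n - my * my
        r2 = (cov * cov) / (vx * vy)
        # variance tolerance guards float residue on monomorphic loci
        r2 = np.where((n >= 2) & (vx > 1e-9) & (vy > 1e-9), r2, np.nan)
    return r2


def r2_matrix(
    gm: GenotypeMatrix, region: Region, samples: list[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full pairwise r² over the region's loci (diagonal = 1).

    Returns (matrix, locus frame); undefined entries are NaN.
    """
    sub = gm.subset_loci(gm.region_mask(region))
    if samples is not None:
        sub = sub.subset_samples(samples)
    if sub.n_loci < 2:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} holds < 2 loci")
    out = pairwise_r2(sub.codes)
    np.fill_diagonal(out, 1.0)
    return out, sub.loci


def ld_decay(
    gm: GenotypeMatrix,
    region: Region,
    max_dist: int,
    bin_size: int,
    sheet: SampleSheet | None = None,
    sex: str | None = None,
) -> pd.DataFrame:
    """Distance-binned mean r² over locus pairs within ``region``.

    ``sex`` optionally restricts the samples to one sex (needs ``sheet``).
    Bins with no pairs are omitted.  Returns a DataFrame with columns
    bin_start, bin_end, n_pairs, mean_r2.
    """
    sub = gm.subset_loci(gm.region_mask(region))
    if sex is not None:
        if sheet is None:
            raise ValueError("restricting by sex requires a sample sheet")
        sub = sub.subset_samples(sheet.ids_of_sex(sex))
    pos = sub.loci["pos"].to_numpy()
    n_bins = int(np.ceil(max_dist / bin_size))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    block = 512
    for a in range(0, sub.n_loci, block):
        b_end = min(a + block, sub.n_loci)
        # partner loci reachable within max_dist of any row in the block
        j_max = int(np.searchsorted(pos, pos[b_end - 1] + max_dist, side="right"))
        r2 = pairwise_r2(sub.codes[a:j_max])
        rows, cols = np.triu_indices(j_max - a, k=1)
        in_block = rows < (b_end - a)
        rows, cols = rows[in_block], cols[in_block]
        d = pos[a + cols] - pos[a + rows]
        vals = r2[rows, cols]
        ok = (d <= max_dist) & ~np.isnan(vals)
        bins = np.minimum(d[ok] // bin_size, n_bins - 1).astype(int)
        np.add.at(sums, bins, vals[ok])
        np.add.at(counts, bins, 1)
    rows = [
        (b * bin_size, min((b + 1) * bin_size, max_dist), counts[b], sums[b] / counts[b])
        for b in range(n_bins)
        if counts[b] > 0
    ]
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "n_pairs", "mean_r2"])
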