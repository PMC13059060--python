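"""Weir & Cockerham (1984) F_ST between two groups, per site and windowed.

The per-site estimator decomposes allele-frequency variance into the
among-group (a), among-individual-within-group (b) and within-individual
(c) components; F_ST = a / (a + b + c).  Negative per-site estimates are a
finite-sample property and are retained, never clipped.  Windowed values
default to the ratio-of-sums ("weighted") form sum(a) / sum(a+b+c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleSheet, WindowTrack, assign_windows

__all__ = ["SiteFstComponents", "wc_site_components", "site_components", "windowed_fst"]


@dataclass(frozen=True)
class SiteFstComponents:
    a: float
    b: float
    c: float

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0 or np.isnan(denom):
            return float("nan")
        return self.a / denom


def _group_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called, alt freq, het freq) for one group; codes int8 2-D."""
    called = codes >= 0
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, codes, 0).sum(axis=1) / (2 * n)
        h = np.where(called, codes == 1, False).sum(axis=1) / n
    return n, p, h


def site_components(
    codes: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized W&C components for every site (rows of ``codes``).

    ``group1`` / ``group2`` are column index arrays.  Sites where a group
    has no called genotype, or where the estimator's n-bar - 1 term is
    degenerate (a single individual per group on average), yield NaN.
    """
    codes = np.atleast_2d(codes)
    r = 2.0
    n1, p1, h1 = _group_stats(codes[:, group1])
    n2, p2, h2 = _group_stats(codes[:, group2])
    valid = (n1 > 0) & (n2 > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    valid &= (nbar > 1.0) & (nc > 0)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_site_components(genotypes1, genotypes2) -> SiteFstComponents:
    """W&C components for one biallelic site from two groups of genotype codes.

    Codes follow the package convention (-1 missing, 0/1/2 dosage); missing
    calls are excluded from the group counts.
    """
    g1 = np.asarray(genotypes1, dtype=np.int8)
    g2 = np.asarray(genotypes2, dtype=np.int8)
    codes = np.concatenate([g1, g2])[None, :]
    idx1 = np.arange(len(g1))
    idx2 = np.arange(len(g1), len(g1) + len(g2))
    a, b, c = site_components(codes, idx1, idx2)
    return SiteFstComponents(float(a[0]), float(b[0]), float(c[0]))


def sex_fst_components(gm: GenotypeMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-site components for the F-vs-M contrast, as a DataFrame
    (chrom, pos, a, b, c, fst)."""
    sheet.require_both_sexes()
    gm.validate_samples(sheet)
    f_idx = gm.sample_indices(sheet.ids_of_sex("F"))
    m_idx = gm.sample_indices(sheet.ids_of_sex("M"))
    a, b, c = site_components(gm.codes, f_idx, m_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame(
        {
            "chrom": gm.loci["chrom"],
            "pos": gm.loci["pos"],
            "a": a,
            "b": b,
            "c": c,
            "fst": fst,
        }
    )


def windowed_fst(
    components: pd.DataFrame,
    windows: pd.DataFrame,
    mode: str = "weighted",
) -> np.ndarray:
    """Aggregate per-site components onto a window grid.

    ``weighted``: sum(a) / sum(a+b+c) over the window's defined sites;
    ``mean``: average of the defined per-site ratios.  Windows with no
    defined site are NaN.
    """
    if mode not in ("weighted", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = assign_windows(
        windows, components["chrom"].to_numpy(), components["pos"].to_numpy()
    )
    a = components["a"].to_numpy(dtype=float)
    denom = a + components["b"].to_numpy(dtype=float) + components["c"].to_numpy(dtype=float)
    defined = (idx >= 0) & ~np.isnan(denom) & (denom != 0)

    out = np.full(len(windows), np.nan)
    if mode == "weighted":
        num = np.bincount(idx[defined], weights=a[defined], minlength=len(windows))
        den = np.bincount(idx[defined], weights=denom[defined], minlength=len(windows))
        nz = den != 0
        out[nz] = num[nz] / den[nz]
        counted = np.bincount(idx[defined], minlength=len(windows))
        out[counted == 0] = np.nan
    else:
        ratio = a[defined] / denom[defined]
        count = np.bincount(idx[defined], minlength=len(windows))
        total = np.bincount(idx[defined], weights=ratio, minlength=len(windows))
        nz = count > 0
        out[nz] = total[nz] / count[nz]
    return out
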