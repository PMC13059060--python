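"""Per-locus sex-linkage classification and heatmap-matrix construction.

A locus is "XY-like" when all called females share one homozygous genotype
and called males are enriched for heterozygotes; "XY-strict" additionally
requires every called male to be heterozygous.  "ZW-strict" is the same
screen with the sexes swapped.  The criteria depend only on homozygote/
heterozygote status, so they are invariant to REF/ALT relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleSheet, assign_windows

XY_LIKE = "xy_like"
XY_STRICT = "xy_strict"
ZW_STRICT = "zw_strict"
NONE = "none"


@dataclass
class LocusClassConfig:
    mode: str = "relaxed"  # relaxed | strict | zw_strict
    min_called_per_sex: int = 3
    male_het_enrichment: float = 0.5  # relaxed mode only

    def __post_init__(self) -> None:
        if self.mode not in ("relaxed", "strict", "zw_strict"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.male_het_enrichment <= 1.0:
            raise ValueError("male_het_enrichment must be in [0, 1]")


def classify_loci(
    gm: GenotypeMatrix, sheet: SampleSheet, cfg: LocusClassConfig | None = None
) -> pd.DataFrame:
    """Classify every locus; returns a DataFrame aligned with ``gm.loci``
    (chrom, pos, label, called_f, called_m, male_het_frac).

    In ``zw_strict`` mode the roles of the sexes are swapped (all females
    heterozygous, all males fixed homozygous) and matching loci are labelled
    ``zw_strict``.
    """
    cfg = cfg or LocusClassConfig()
    sheet.require_both_sexes()
    gm.validate_samples(sheet)
    f = gm.codes[:, gm.sample_indices(sheet.ids_of_sex("F"))]
    m = gm.codes[:, gm.sample_indices(sheet.ids_of_sex("M"))]
    if cfg.mode == "zw_strict":
        f, m = m, f

    f_called = (f >= 0).sum(axis=1)
    m_called = (m >= 0).sum(axis=1)
    enough = (f_called >= cfg.min_called_per_sex) & (m_called >= cfg.min_called_per_sex)

    hom = (f == 0) | (f == 2)
    called_f = f >= 0
    # all called females homozygous for one and the same genotype
    first = np.where(called_f.any(axis=1), f[np.arange(len(f)), called_f.argmax(axis=1)], -1)
    f_fixed_hom = (
        called_f.any(axis=1)
        & (hom | ~called_f).all(axis=1)
        & ((f == first[:, None]) | ~called_f).all(axis=1)
    )

    m_het = ((m == 1).sum(axis=1)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        male_het_frac = np.where(m_called > 0, m_het / m_called, np.nan)
    all_m_het = (m_called > 0) & (((m == 1) | (m < 0)).all(axis=1))

    labels = np.full(gm.n_loci, NONE, dtype=object)
    if cfg.mode == "relaxed":
        like = enough & f_fixed_hom & (male_het_frac >= cfg.male_het_enrichment)
        strict = like & all_m_het
        labels[like] = XY_LIKE
        labels[strict] = XY_STRICT
    elif cfg.mode == "strict":
        strict = enough & f_fixed_hom & all_m_het
        labels[strict] = XY_STRICT
    else:
        strict = enough & f_fixed_hom & all_m_het
        labels[strict] = ZW_STRICT

    return pd.DataFrame(
        {
            "chrom": gm.loci["chrom"],
            "pos": gm.loci["pos"],
            "label": labels,
            "called_f": f_called if cfg.mode != "zw_strict" else m_called,
            "called_m": m_called if cfg.mode != "zw_strict" else f_called,
            "male_het_frac": male_het_frac,
        }
    )


def sex_snp_window_counts(classes: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Per-window count of classified (label != none) loci."""
    informative = classes["label"].to_numpy() != NONE
    idx = assign_windows(
        windows, classes["chrom"].to_numpy(), classes["pos"].to_numpy()
    )
    keep = informative & (idx >= 0)
    return np.bincount(idx[keep], minlength=len(windows)).astype(float)


def heatmap_matrix(
    gm: GenotypeMatrix,
    locus_mask: np.ndarray,
    sheet: SampleSheet,
    n_subsample: int = 20_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Build the genotype matrix behind the SLR heatmap figures.

    Takes a boolean mask (or index array) of classified loci, subsamples
    uniformly without replacement to ``n_subsample`` rows when larger, sorts
    rows by (chrom, pos), and orders columns females first, then M1 males,
    then M2 males, then unlabelled males.  Returns (matrix frame with
    genotype codes, locus frame, ordered sample ids); missing stays -1.
    """
    sub = gm.subset_loci(np.asarray(locus_mask))
    if sub.n_loci == 0:
        raise ValueError("no loci selected for the heatmap")
    if sub.n_loci > n_subsample:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(sub.n_loci, size=n_subsample, replace=False))
        sub = sub.subset_loci(pick)
    ordered = (
        sheet.ids_of_sex("F")
        + sheet.ids_of_class("M1")
        + sheet.ids_of_class("M2")
        + sheet.ids_of_class("unknown")
    )
    ordered = [s for s in ordered if s in sub.samples]
    sub = sub.subset_samples(ordered)
    matrix = pd.DataFrame(sub.codes, columns=ordered)
    return matrix, sub.loci, ordered
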