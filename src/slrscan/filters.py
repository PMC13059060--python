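"""Variant-level preprocessing: MAF/missingness filters, LD pruning, and the
within-sex genotype-consistency screen that isolates the XY inheritance
pattern (male heterozygous, female homozygous)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, SampleSheet
from .ld import pairwise_r2

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_maf: float = 0.05
    max_missing_frac: float = 0.25
    ld_prune_window: int = 50  # SNP count
    ld_prune_step: int = 10  # SNP count
    ld_prune_r2: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")


def filter_maf_missing(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Drop loci with minor-allele frequency < ``min_maf`` (boundary kept) or
    missing-call fraction > ``max_missing_frac`` (boundary kept).

    MAF is computed by allele counting over called genotypes only.
    """
    called = gm.codes >= 0
    n_called = called.sum(axis=1)
    missing_frac = 1.0 - n_called / gm.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gm.codes, 0).sum(axis=1) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_called > 0, maf, 0.0)
    keep = (maf >= cfg.min_maf) & (missing_frac <= cfg.max_missing_frac)
    log.info(
        "maf/missing filter: kept %d of %d loci (min_maf=%g, max_missing=%g)",
        int(keep.sum()),
        gm.n_loci,
        cfg.min_maf,
        cfg.max_missing_frac,
    )
    if not keep.any():
        log.warning("maf/missing filter removed every locus")
    return gm.subset_loci(keep)


def ld_prune(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage r².

    Within each window of ``ld_prune_window`` consecutive kept SNPs
    (advancing by ``ld_prune_step``), pairs with r² > ``ld_prune_r2`` lose
    one member: the SNP with more missing calls, or on a tie the
    later-positioned one.  Passes repeat until no SNP is removed, which
    makes the operation idempotent.
    """
    n = gm.n_loci
    keep = np.ones(n, dtype=bool)
    n_missing = (gm.codes < 0).sum(axis=1)
    # loci are sorted per-chromosome; windows never straddle chromosomes
    chrom_bounds: list[tuple[int, int]] = []
    chroms = gm.loci["chrom"].to_numpy()
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            chrom_bounds.append((start, i))
            start = i

    def one_pass() -> bool:
        changed = False
        for lo, hi in chrom_bounds:
            kept = [i for i in range(lo, hi) if keep[i]]
            w_start = 0
            while w_start < len(kept):
                idx = kept[w_start : w_start + cfg.ld_prune_window]
                r2 = pairwise_r2(gm.codes[idx])
                for ai in range(len(idx)):
                    i = idx[ai]
                    if not keep[i]:
                        continue
                    for bi in range(ai + 1, len(idx)):
                        j = idx[bi]
                        if not keep[j] or not keep[i]:
                            continue
                        if not r2[ai, bi] > cfg.ld_prune_r2:  # NaN-safe
                            continue
                        if n_missing[i] > n_missing[j]:
                            keep[i] = False
                        else:  # more missing at j, or tie -> later position
                            keep[j] = False
                        changed = True
                if w_start + cfg.ld_prune_window >= len(kept):
                    break
                w_start += cfg.ld_prune_step
        return changed

    while one_pass():
        pass
    log.info("LD pruning: kept %d of %d loci (r2 > %g removed)", int(keep.sum()), n, cfg.ld_prune_r2)
    return gm.subset_loci(keep)


def consistency_filter(
    gm: GenotypeMatrix, sheet: SampleSheet
) -> tuple[np.ndarray, np.ndarray]:
    """Within-sex genotype-consistency screen.

    Returns two boolean masks over loci: ``retained`` (no missing call
    anywhere, all males share one genotype AND all females share one
    genotype) and its ``xy_pattern`` subset (shared male genotype
    heterozygous, shared female genotype homozygous).
    """
    sheet.require_both_sexes()
    gm.validate_samples(sheet)
    f = gm.codes[:, gm.sample_indices(sheet.ids_of_sex("F"))]
    m = gm.codes[:, gm.sample_indices(sheet.ids_of_sex("M"))]
    no_missing = (gm.codes >= 0).all(axis=1)
    f_consistent = (f == f[:, :1]).all(axis=1)
    m_consistent = (m == m[:, :1]).all(axis=1)
    retained = no_missing & f_consistent & m_consistent
    xy_pattern = retained & (m[:, 0] == 1) & ((f[:, 0] == 0) | (f[:, 0] == 2))
    log.info(
        "consistency filter: retained %d of %d loci, %d with the XY pattern",
        int(retained.sum()),
        gm.n_loci,
        int(xy_pattern.sum()),
    )
    return retained, xy_pattern
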