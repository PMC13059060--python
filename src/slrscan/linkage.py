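"""Per-individual sex-linkage scores over a fixed XY-like locus panel, and
the cross-chromosome co-occurrence test.

A panel is defined a priori from a defining contrast (e.g. the 5 females vs
the 5 strongly differentiated M2 males) inside one region.  Every cohort
member is then scored as the proportion of heterozygous calls across panel
loci.  Because panel loci require all defining females to be fixed
homozygous, each defining female scores exactly 0 on her own panel.
Dichotomized scores from two panels feed a 2x2 Fisher exact test; the raw
scores feed a Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import NONE, LocusClassConfig, classify_loci
from .core import GenotypeMatrix, Region, SampleSheet

log = logging.getLogger(__name__)


@dataclass
class LocusPanel:
    """The loci defining a per-individual sex-linkage score."""

    region: Region
    mode: str
    locus_mask: np.ndarray  # boolean over the defining GenotypeMatrix rows
    loci: pd.DataFrame  # chrom/pos/ref/alt of panel members
    defining_samples: list[str]

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class CooccurrenceConfig:
    thr_a: float = 0.6  # dichotomization threshold for panel A (score >= thr -> high)
    thr_b: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.thr_a <= 1.0 and 0.0 <= self.thr_b <= 1.0):
            raise ValueError("thresholds must be in [0, 1]")


@dataclass
class CooccurrenceResult:
    table: np.ndarray  # 2x2: rows a-state (high, low), cols b-state (high, low)
    fisher_p: float
    spearman_rho: float
    spearman_p: float
    n_discordant: int
    n_excluded: int = 0
    samples: list[str] = field(default_factory=list)


def build_panel(
    gm: GenotypeMatrix,
    sheet: SampleSheet,
    region: Region,
    mode: str = "relaxed",
    defining_samples: list[str] | None = None,
    cfg: LocusClassConfig | None = None,
) -> LocusPanel:
    """Classify loci inside ``region`` using only the defining samples.

    ``mode`` "relaxed" keeps XY-like loci (which include the strict ones);
    "strict" keeps only all-male-heterozygous loci.  The default defining
    cohort is all females plus the M2 males (the F-vs-M2 contrast).
    """
    if defining_samples is None:
        defining_samples = sheet.ids_of_sex("F") + sheet.ids_of_class("M2")
    sub_sheet = sheet.subset(defining_samples)
    sub_sheet.require_both_sexes()
    region_mask = gm.region_mask(region)
    sub = gm.subset_loci(region_mask).subset_samples(defining_samples)
    cfg = cfg or LocusClassConfig(mode=mode)
    if cfg.mode != mode:
        cfg = LocusClassConfig(mode=mode, min_called_per_sex=cfg.min_called_per_sex,
                               male_het_enrichment=cfg.male_het_enrichment)
    classes = classify_loci(sub, sub_sheet, cfg)
    selected = classes["label"].to_numpy() != NONE
    if not selected.any():
        log.warning(
            "empty panel for %s:%d-%d (%s mode)", region.chrom, region.start, region.end, mode
        )
    mask = np.zeros(gm.n_loci, dtype=bool)
    mask[np.flatnonzero(region_mask)[selected]] = True
    return LocusPanel(
        region=region,
        mode=mode,
        locus_mask=mask,
        loci=gm.loci.loc[mask].reset_index(drop=True),
        defining_samples=list(defining_samples),
    )


def sample_scores(gm: GenotypeMatrix, panel: LocusPanel) -> pd.DataFrame:
    """Score every sample on the panel: score = n_het / n_called.

    Samples with no called panel locus get a NaN score (flagged by
    n_called = 0).  Returns a DataFrame (sample_id, n_called, n_het, score).
    """
    sub = gm.subset_loci(panel.locus_mask)
    called = (sub.codes >= 0).sum(axis=0)
    het = (sub.codes == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.DataFrame(
        {"sample_id": sub.samples, "n_called": called, "n_het": het, "score": score}
    )


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one.  An
    all-zero table has p = 1.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if table.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    p is two-sided from the t-approximation on n-2 degrees of freedom;
    rho = +/-1 yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")  # zero rank variance
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if np.isnan(rho):
        return rho, float("nan")
    if abs(rho) == 1.0:
        return rho, 0.0
    return rho, float(res.pvalue)


def cooccurrence(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    cfg: CooccurrenceConfig | None = None,
) -> CooccurrenceResult:
    """Co-occurrence of high sex-linkage scores across two panels.

    Scores are matched by sample id, dichotomized at their panel thresholds
    (>= means high), tabulated 2x2 for a Fisher exact test, and correlated
    (Spearman) on the raw values.  Samples with an undefined score on either
    panel are excluded pairwise (a count is logged).
    """
    cfg = cfg or CooccurrenceConfig()
    merged = scores_a.merge(scores_b, on="sample_id", suffixes=("_a", "_b"))
    if len(merged) != len(scores_a) or len(merged) != len(scores_b):
        raise ValueError("score sets cover different samples")
    ok = ~(merged["score_a"].isna() | merged["score_b"].isna())
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("co-occurrence: excluded %d samples with undefined scores", n_excluded)
    merged = merged[ok]
    a_high = merged["score_a"].to_numpy() >= cfg.thr_a
    b_high = merged["score_b"].to_numpy() >= cfg.thr_b
    table = np.array(
        [
            [int((a_high & b_high).sum()), int((a_high & ~b_high).sum())],
            [int((~a_high & b_high).sum()), int((~a_high & ~b_high).sum())],
        ]
    )
    if len(merged) >= 3:
        rho, sp_p = spearman(merged["score_a"].to_numpy(), merged["score_b"].to_numpy())
    else:
        rho, sp_p = float("nan"), float("nan")
    return CooccurrenceResult(
        table=table,
        fisher_p=fisher_exact_2x2(table),
        spearman_rho=rho,
        spearman_p=sp_p,
        n_discordant=int(table[0, 1] + table[1, 0]),
        n_excluded=n_excluded,
        samples=merged["sample_id"].tolist(),
    )
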