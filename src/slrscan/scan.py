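"""Genome-wide window tracks (F_ST, log2 coverage ratio, SNP density) and
candidate-SLR calling by the top-quantile F_ST rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    SLR_CANDIDATE,
    DepthTable,
    GenotypeMatrix,
    Region,
    SampleSheet,
    WindowTrack,
    assign_windows,
    merge_flagged_runs,
)
from .fst import sex_fst_components, windowed_fst


@dataclass
class WindowScanConfig:
    window_size: int = 50_000
    pseudocount: float = 0.01
    fst_quantile: float = 0.99
    min_flagged_windows: int = 2
    max_gap_windows: int = 1
    fst_mode: str = "weighted"  # or "mean"
    density_definition: str = "polymorphic"  # or "alt_carrier"
    quantile_scope: str = "genome"  # or "chromosome"

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_quantile < 1.0:
            raise ValueError("fst_quantile must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def depth_log2_ratio(
    depth: DepthTable, sheet: SampleSheet, cfg: WindowScanConfig | None = None
) -> np.ndarray:
    """Per-window log2(male coverage + eps) - log2(female coverage + eps).

    Coverage per sex is the mean depth over that sex's samples; the
    pseudocount eps guards zero coverage (a fully hemizygous window with
    16x male / 0x female coverage scores log2(16.01/0.01) ~ 10.6).
    """
    cfg = cfg or WindowScanConfig()
    sheet.require_both_sexes()
    eps = cfg.pseudocount
    m = depth.depth[:, depth.sample_indices(sheet.ids_of_sex("M"))].mean(axis=1)
    f = depth.depth[:, depth.sample_indices(sheet.ids_of_sex("F"))].mean(axis=1)
    return np.log2(m + eps) - np.log2(f + eps)


def _polymorphic_within(codes: np.ndarray) -> np.ndarray:
    """Per-locus: both alleles observed among called genotypes of the group."""
    called = codes >= 0
    any_ref = ((codes == 0) | (codes == 1)) & called
    any_alt = ((codes == 2) | (codes == 1)) & called
    return any_ref.any(axis=1) & any_alt.any(axis=1)


def _alt_carrier(codes: np.ndarray) -> np.ndarray:
    return ((codes == 1) | (codes == 2)).any(axis=1)


def snp_density_tracks(
    gm: GenotypeMatrix,
    windows: pd.DataFrame,
    sheet: SampleSheet,
    cfg: WindowScanConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-window, per-sex SNP density (loci per Mb) and their log2 ratio.

    A locus counts for a sex if it is polymorphic within that sex's called
    genotypes (default) or if any sample of that sex carries the alt allele
    (``density_definition="alt_carrier"``).
    """
    cfg = cfg or WindowScanConfig()
    sheet.require_both_sexes()
    mark = _polymorphic_within if cfg.density_definition == "polymorphic" else _alt_carrier
    idx = assign_windows(windows, gm.loci["chrom"].to_numpy(), gm.loci["pos"].to_numpy())
    w_mb = (windows["end"] - windows["start"]).to_numpy() / 1e6
    out: dict[str, np.ndarray] = {}
    for sex, name in (("M", "snp_density_m"), ("F", "snp_density_f")):
        codes = gm.codes[:, gm.sample_indices(sheet.ids_of_sex(sex))]
        keep = mark(codes) & (idx >= 0)
        counts = np.bincount(idx[keep], minlength=len(windows))
        out[name] = counts / w_mb
    eps = cfg.pseudocount
    out["log2_snp_ratio"] = np.log2(
        (out["snp_density_m"] + eps) / (out["snp_density_f"] + eps)
    )
    return out


def build_track(
    gm: GenotypeMatrix,
    depth: DepthTable,
    sheet: SampleSheet,
    cfg: WindowScanConfig | None = None,
) -> WindowTrack:
    """Assemble the full scan track: windowed F_ST, log2 coverage ratio,
    and SNP-density columns, on the depth table's window grid."""
    cfg = cfg or WindowScanConfig()
    track = WindowTrack(depth.windows)
    comps = sex_fst_components(gm, sheet)
    track.add("fst", windowed_fst(comps, depth.windows, mode=cfg.fst_mode))
    track.add("log2_cov_ratio", depth_log2_ratio(depth, sheet, cfg))
    for name, col in snp_density_tracks(gm, depth.windows, sheet, cfg).items():
        track.add(name, col)
    return track


def call_slr(track: WindowTrack, cfg: WindowScanConfig | None = None) -> list[Region]:
    """Flag windows in the top F_ST quantile and merge them into candidate
    SLR regions.

    The threshold is the empirical ``fst_quantile`` (linear interpolation
    between order statistics) of the non-missing windowed F_ST, computed
    genome-wide or per chromosome (``quantile_scope``).  Flagged windows
    separated by <= ``max_gap_windows`` unflagged windows merge; merged runs
    with fewer than ``min_flagged_windows`` flagged windows are dropped.
    Region score = mean F_ST over the run.
    """
    cfg = cfg or WindowScanConfig()
    if "fst" not in track:
        raise ValueError("track has no 'fst' column")
    fst = track["fst"]
    if np.sum(~np.isnan(fst)) < 10:
        raise ValueError("need >= 10 non-missing F_ST windows to set a quantile threshold")
    flagged = np.zeros(len(fst), dtype=bool)
    if cfg.quantile_scope == "genome":
        thr = np.nanquantile(fst, cfg.fst_quantile)
        flagged = fst >= thr
    else:
        chroms = track.windows["chrom"].to_numpy()
        for chrom in dict.fromkeys(chroms):
            m = chroms == chrom
            if np.sum(~np.isnan(fst[m])) == 0:
                continue
            thr = np.nanquantile(fst[m], cfg.fst_quantile)
            flagged[m] = fst[m] >= thr
    flagged &= ~np.isnan(fst)
    return merge_flagged_runs(
        track.windows,
        flagged,
        max_gap_windows=cfg.max_gap_windows,
        min_flagged_windows=cfg.min_flagged_windows,
        label=SLR_CANDIDATE,
        score_from=fst,
    )
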