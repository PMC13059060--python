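"""Coverage-based extraction of male-specific (Y-specific) and hemizygous
regions from per-window depth profiles.

A window is male-specific when every female is at (or below) the female
depth ceiling while enough males are well covered; running the same screen
with the sexes swapped yields the female-specific (ZW-direction) regions.
Hemizygous regions are runs of windows whose log2(M:F) coverage ratio
exceeds a threshold — with the 0.01 pseudocount, a threshold of 3
corresponds to at least an eight-fold male excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    HEMIZYGOUS,
    MALE_SPECIFIC,
    DepthTable,
    Region,
    SampleSheet,
    WindowTrack,
    merge_flagged_runs,
)


@dataclass
class MarkerConfig:
    min_male_depth: float = 5.0
    max_female_depth: float = 0.0
    min_male_fraction: float = 1.0
    min_length: int | None = None  # bp; default one window
    merge_gap: int | None = None  # bp; default one window
    hemi_log2_threshold: float = 3.0
    hemi_min_windows: int = 2

    def __post_init__(self) -> None:
        for name in ("min_male_depth", "max_female_depth", "hemi_log2_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.min_male_fraction <= 1.0:
            raise ValueError("min_male_fraction must be in [0, 1]")


def _window_size(windows: pd.DataFrame) -> int:
    return int((windows["end"] - windows["start"]).max())


def male_specific_regions(
    depth: DepthTable, sheet: SampleSheet, cfg: MarkerConfig | None = None
) -> list[Region]:
    """Windows covered essentially only by male reads, merged into regions.

    A window is flagged when every female's depth <= ``max_female_depth``
    and at least ``min_male_fraction`` of males have depth >=
    ``min_male_depth``.  Flagged windows closer than ``merge_gap`` bp merge;
    regions shorter than ``min_length`` bp are dropped.  Swapping the sex
    labels in ``sheet`` turns this into the female-specific screen.
    """
    cfg = cfg or MarkerConfig()
    sheet.require_both_sexes()
    w = _window_size(depth.windows)
    min_length = cfg.min_length if cfg.min_length is not None else w
    merge_gap = cfg.merge_gap if cfg.merge_gap is not None else w

    f = depth.depth[:, depth.sample_indices(sheet.ids_of_sex("F"))]
    m = depth.depth[:, depth.sample_indices(sheet.ids_of_sex("M"))]
    females_absent = (f <= cfg.max_female_depth).all(axis=1)
    male_frac = (m >= cfg.min_male_depth).mean(axis=1)
    flagged = females_absent & (male_frac >= cfg.min_male_fraction)

    regions = merge_flagged_runs(
        depth.windows,
        flagged,
        max_gap_windows=max(merge_gap // w, 0),
        min_flagged_windows=1,
        label=MALE_SPECIFIC,
    )
    return [r for r in regions if r.length >= min_length]


def hemizygous_regions(track: WindowTrack, cfg: MarkerConfig | None = None) -> list[Region]:
    """Runs of >= ``hemi_min_windows`` windows with log2(M:F) coverage ratio
    >= ``hemi_log2_threshold``."""
    cfg = cfg or MarkerConfig()
    if "log2_cov_ratio" not in track:
        raise ValueError("track has no 'log2_cov_ratio' column")
    ratio = track["log2_cov_ratio"]
    flagged = ~np.isnan(ratio) & (ratio >= cfg.hemi_log2_threshold)
    w = _window_size(track.windows)
    merge_gap = cfg.merge_gap if cfg.merge_gap is not None else w
    return merge_flagged_runs(
        track.windows,
        flagged,
        max_gap_windows=max(merge_gap // w, 0),
        min_flagged_windows=cfg.hemi_min_windows,
        label=HEMIZYGOUS,
        score_from=ratio,
    )
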