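"""Binary segmentation for change-points in the mean of a windowed series.

Greedy recursion: at each step, the segment offering the largest reduction
in total within-segment sum of squared deviations is split at its best
point (ties -> leftmost).  Stopping is either a fixed number of
change-points Q, or an SIC-style penalty that stops when the best reduction
falls below beta = log(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChangepointConfig:
    max_changepoints: int = 5
    penalty: str = "none"  # "none" (fixed Q) or "sic" (beta = log n)
    min_segment: int = 2  # windows

    def __post_init__(self) -> None:
        if self.max_changepoints < 0:
            raise ValueError("max_changepoints must be >= 0")
        if self.penalty not in ("none", "sic"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")


@dataclass
class ChangepointResult:
    breakpoints: list[int]  # last index (0-based, inclusive) of each segment but the final one
    segment_means: list[float]

    @property
    def segments(self) -> list[tuple[int, int]]:
        """(start, end) half-open index ranges of each segment."""
        bounds = [0] + [b + 1 for b in self.breakpoints]
        return list(zip(bounds, bounds[1:] + [None]))  # type: ignore[list-item]


def _best_split(
    cs: np.ndarray, cs2: np.ndarray, lo: int, hi: int, min_segment: int
) -> tuple[int, float] | None:
    """Best single split of segment [lo, hi) minimizing summed SSE.

    Returns (split index m so that children are [lo, m) and [m, hi),
    SSE reduction) or None when the segment cannot be split.
    """
    n = hi - lo
    if n < 2 * min_segment:
        return None

    def sse(i: int, j: int) -> float:
        s = cs[j] - cs[i]
        s2 = cs2[j] - cs2[i]
        return s2 - s * s / (j - i)

    parent = sse(lo, hi)
    best_m, best_red = -1, -np.inf
    for m in range(lo + min_segment, hi - min_segment + 1):
        red = parent - (sse(lo, m) + sse(m, hi))
        if red > best_red + 1e-12:  # strict improvement; ties keep leftmost
            best_m, best_red = m, red
    if best_m < 0:
        return None
    return best_m, best_red


def binseg_mean(series: np.ndarray, cfg: ChangepointConfig | None = None) -> ChangepointResult:
    """Greedy binary segmentation of ``series`` for mean changes."""
    cfg = cfg or ChangepointConfig()
    x = np.asarray(series, dtype=float)
    n = len(x)
    if np.any(np.isnan(x)):
        raise ValueError("series contains NaN; impute or drop before segmentation")
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    boundaries = [0, n]
    if n >= 2 * cfg.min_segment:
        # a split must strictly reduce the cost; SIC additionally demands
        # the reduction exceed log(n)
        beta = np.log(n) if cfg.penalty == "sic" else 1e-12
        for _ in range(cfg.max_changepoints):
            best = None  # (reduction, split, lo)
            for lo, hi in zip(boundaries, boundaries[1:]):
                cand = _best_split(cs, cs2, lo, hi, cfg.min_segment)
                if cand is None:
                    continue
                m, red = cand
                # pick the largest reduction; ties -> leftmost split
                if best is None or red > best[0] + 1e-12:
                    best = (red, m, lo)
            if best is None or best[0] < beta:
                break
            boundaries = sorted(boundaries + [best[1]])

    means = [float(x[lo:hi].mean()) for lo, hi in zip(boundaries, boundaries[1:])]
    breakpoints = [b - 1 for b in boundaries[1:-1]]
    return ChangepointResult(breakpoints=breakpoints, segment_means=means)
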