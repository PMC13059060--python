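"""Core in-memory containers shared by every pipeline stage.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open ``[start, end)``.  VCF
positions (1-based) are converted on read and back-converted on write; no
other module performs coordinate arithmetic on 1-based values.

Genotype codes
--------------
Diploid genotypes are stored as ``int8`` alt-allele dosages with a missing
sentinel::

    -1  missing (any allele missing, e.g. ./., .|0)
     0  homozygous reference (0/0)
     1  heterozygous (0/1 or 1/0; phase is ignored)
     2  homozygous alternate (1/1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: labels carried by :class:`Region`
SLR_CANDIDATE = "SLR_CANDIDATE"
MALE_SPECIFIC = "MALE_SPECIFIC"
HEMIZYGOUS = "HEMIZYGOUS"


@dataclass(frozen=True)
class Region:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = SLR_CANDIDATE
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def contains(self, chrom: str, pos: float) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class SampleSheet:
    """Sample metadata: id, phenotypic sex, optional population / male class.

    ``sex`` is "F" or "M"; ``male_class`` is "M1", "M2" or "unknown" and is
    meaningful for males only.
    """

    VALID_SEX = {"F", "M"}
    VALID_CLASS = {"M1", "M2", "unknown"}

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "sample_id" not in frame.columns or "sex" not in frame.columns:
            raise ValueError("sample sheet needs 'sample_id' and 'sex' columns")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        bad = set(frame["sex"]) - self.VALID_SEX
        if bad:
            raise ValueError(f"unknown sex token(s): {sorted(bad)}")
        if "population" not in frame.columns:
            frame["population"] = None
        if "male_class" not in frame.columns:
            frame["male_class"] = "unknown"
        frame["male_class"] = frame["male_class"].fillna("unknown")
        bad = set(frame["male_class"]) - self.VALID_CLASS
        if bad:
            raise ValueError(f"unknown male_class token(s): {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def sex_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["sex"]))

    def ids_of_sex(self, sex: str) -> list[str]:
        return self.frame.loc[self.frame["sex"] == sex, "sample_id"].tolist()

    def ids_of_class(self, male_class: str) -> list[str]:
        m = (self.frame["sex"] == "M") & (self.frame["male_class"] == male_class)
        return self.frame.loc[m, "sample_id"].tolist()

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet(self.frame[self.frame["sample_id"].isin(keep)])

    def swapped_sexes(self) -> "SampleSheet":
        """Relabel F<->M (used for the ZW-direction screens)."""
        frame = self.frame.copy()
        frame["sex"] = frame["sex"].map({"F": "M", "M": "F"})
        return SampleSheet(frame)

    def require_both_sexes(self) -> None:
        for sex in ("F", "M"):
            if not self.ids_of_sex(sex):
                raise ValueError(f"no samples of sex {sex!r}; a sex contrast needs both")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSheet):
            return NotImplemented
        return self.frame.fillna("").equals(other.frame.fillna(""))


LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeMatrix:
    """Biallelic-SNP genotypes: loci x samples dosage codes.

    ``loci`` is a DataFrame with columns chrom, pos (0-based), ref, alt,
    sorted by (chrom, pos); ``codes`` is an int8 array of shape
    ``(n_loci, n_samples)`` over {-1, 0, 1, 2}.
    """

    def __init__(self, loci: pd.DataFrame, samples: Sequence[str], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(loci), len(samples)):
            raise ValueError(
                f"codes shape {codes.shape} != (n_loci={len(loci)}, n_samples={len(samples)})"
            )
        if not set(np.unique(codes)) <= {-1, 0, 1, 2}:
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        loci = loci.reset_index(drop=True)
        order = loci.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        self.loci = loci.loc[order].reset_index(drop=True)
        self.codes = codes[order]
        self.samples = list(samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing}")
        return np.array([index[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(self.loci, list(sample_ids), self.codes[:, idx])

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """``keep`` is a boolean mask or integer index over loci rows."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(self.loci.iloc[keep], self.samples, self.codes[keep])

    def region_mask(self, region: Region) -> np.ndarray:
        pos = self.loci["pos"].to_numpy()
        return (
            (self.loci["chrom"].to_numpy() == region.chrom)
            & (pos >= region.start)
            & (pos < region.end)
        ).astype(bool)

    def validate_samples(self, sheet: SampleSheet) -> None:
        if set(self.samples) != set(sheet.sample_ids):
            only_gm = sorted(set(self.samples) - set(sheet.sample_ids))
            only_sheet = sorted(set(sheet.sample_ids) - set(self.samples))
            raise ValueError(
                f"sample sheet / genotype sample mismatch: only in matrix {only_gm}, "
                f"only in sheet {only_sheet}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci.equals(other.loci)
            and np.array_equal(self.codes, other.codes)
        )


WINDOW_COLUMNS = ["chrom", "start", "end"]


def make_windows(chrom_lengths: dict[str, int], window_size: int) -> pd.DataFrame:
    """Tile each chromosome with half-open windows of ``window_size``.

    The last window of a chromosome may be shorter.  Returns a DataFrame
    with columns chrom, start, end and a positional ``index`` column.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_size):
            rows.append((chrom, start, min(start + window_size, length)))
    frame = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    frame["index"] = np.arange(len(frame))
    return frame


def validate_window_grid(windows: pd.DataFrame) -> None:
    """Check that windows tile each chromosome without overlap."""
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError(f"empty window on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping windows on {chrom}")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError(f"window grid on {chrom} is not a contiguous tiling")


def assign_windows(
    windows: pd.DataFrame, chroms: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Map positions to window row indices; -1 for positions off the grid."""
    out = np.full(len(pos), -1, dtype=int)
    for chrom, sub in windows.groupby("chrom", sort=False):
        m = chroms == chrom
        if not m.any():
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        rows = sub.index.to_numpy()
        j = np.searchsorted(starts, pos[m], side="right") - 1
        ok = (j >= 0) & (pos[m] < ends[np.clip(j, 0, len(ends) - 1)])
        vals = np.where(ok, rows[np.clip(j, 0, len(rows) - 1)], -1)
        out[np.flatnonzero(m)] = vals
    return out


class DepthTable:
    """Per-sample mean sequencing depth on a fixed window grid."""

    def __init__(self, windows: pd.DataFrame, samples: Sequence[str], depth: np.ndarray):
        depth = np.asarray(depth, dtype=float)
        if depth.shape != (len(windows), len(samples)):
            raise ValueError(
                f"depth shape {depth.shape} != (n_windows={len(windows)}, n_samples={len(samples)})"
            )
        if np.any(depth < 0):
            raise ValueError("negative depth")
        windows = windows.copy().reset_index(drop=True)
        order = windows.sort_values(["chrom", "start"], kind="stable").index.to_numpy()
        windows = windows.loc[order].reset_index(drop=True)
        windows["index"] = np.arange(len(windows))
        validate_window_grid(windows)
        self.windows = windows[WINDOW_COLUMNS + ["index"]]
        self.samples = list(samples)
        self.depth = depth[order]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from depth table: {missing}")
        return np.array([index[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "DepthTable":
        idx = self.sample_indices(sample_ids)
        return DepthTable(self.windows, list(sample_ids), self.depth[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.windows.equals(other.windows)
            and np.allclose(self.depth, other.depth)
        )


@dataclass
class WindowTrack:
    """Named per-window statistic vectors on a shared window grid.

    Columns are float vectors aligned to ``windows``; NaN marks windows for
    which a statistic is undefined (e.g. no informative site).
    """

    windows: pd.DataFrame
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if len(values) != len(self.windows):
            raise ValueError(f"column {name!r} length {len(values)} != {len(self.windows)} windows")
        self.columns[name] = values

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self.columns

    def to_frame(self) -> pd.DataFrame:
        frame = self.windows[WINDOW_COLUMNS].copy()
        for name, values in self.columns.items():
            frame[name] = values
        return frame


def merge_flagged_runs(
    windows: pd.DataFrame,
    flagged: np.ndarray,
    *,
    max_gap_windows: int,
    min_flagged_windows: int,
    label: str,
    score_from: np.ndarray | None = None,
) -> list[Region]:
    """Merge flagged windows into regions, chromosome by chromosome.

    Runs of flagged windows separated by <= ``max_gap_windows`` unflagged
    windows are merged; merged runs containing fewer than
    ``min_flagged_windows`` flagged windows are dropped.  ``score_from``
    (optional per-window values) yields each region's score as the mean over
    the run's non-NaN values.
    """
    regions: list[Region] = []
    flagged = np.asarray(flagged, dtype=bool)
    for chrom, sub in windows.groupby("chrom", sort=False):
        rows = sub.sort_values("start").index.to_numpy()
        fl = np.flatnonzero(flagged[rows])
        if fl.size == 0:
            continue
        runs: list[list[int]] = [[fl[0]]]
        for i in fl[1:]:
            if i - runs[-1][-1] - 1 <= max_gap_windows:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < min_flagged_windows:
                continue
            span = rows[run[0] : run[-1] + 1]
            start = int(windows.loc[rows[run[0]], "start"])
            end = int(windows.loc[rows[run[-1]], "end"])
            score = None
            if score_from is not None:
                vals = np.asarray(score_from, dtype=float)[span]
                if np.any(~np.isnan(vals)):
                    score = float(np.nanmean(vals))
            regions.append(Region(chrom, start, end, label=label, score=score))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions
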