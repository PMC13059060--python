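"""Forward simulator for male/female resequencing cohorts with planted
sex-linked structure.

The simulator emits the three inputs the pipeline consumes (genotypes,
per-window depth, sample sheet) together with the ground truth used by the
recovery tests: which loci are XY-differential, which intervals are
Y-hemizygous, and each male's Y-haplotype class.

Model
-----
* Autosomal SNPs are placed uniformly at ``autosomal_snp_rate`` per kb with
  alt-allele frequencies drawn from a Beta distribution, and genotypes drawn
  under Hardy-Weinberg equilibrium identically for both sexes.
* ``XY_DIFFERENTIAL`` intervals carry additional SNPs at which every female
  is fixed for one homozygote (0/0 or 1/1, chosen per locus), every M2 male
  is heterozygous, and every M1 male carries the female genotype with
  probability ``m1_y_similarity`` (an X-like, weakly differentiated Y) and
  is heterozygous otherwise.
* ``Y_HEMIZYGOUS`` intervals are Y-specific sequence present only in M2
  males: female and M1 depth is 0 (plus an optional uniform noise floor)
  while M2 depth is drawn like any other window; no SNPs are planted there
  (females have nothing to genotype against).
* Depth per (window, sample) is gamma-mixed Poisson: a gamma multiplier
  with unit mean and variance ``depth_dispersion`` scales ``mean_depth``,
  and read counts are Poisson at that rate.
* Genotype errors flip a call to a uniformly chosen different code with
  probability ``genotype_error``; calls are masked missing with probability
  ``missing_rate``.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    HEMIZYGOUS,
    DepthTable,
    GenotypeMatrix,
    Region,
    SampleSheet,
    make_windows,
)
from . import io as _io

XY_DIFFERENTIAL = "XY_DIFFERENTIAL"
Y_HEMIZYGOUS = "Y_HEMIZYGOUS"
X_LIKE_BACKGROUND = "X_LIKE_BACKGROUND"

_KINDS = {XY_DIFFERENTIAL, Y_HEMIZYGOUS, X_LIKE_BACKGROUND}


@dataclass(frozen=True)
class SlrSpec:
    """A planted sex-linked interval (0-based half-open).

    ``snp_rate`` (SNPs per kb) applies to XY_DIFFERENTIAL intervals: the
    density of planted male-het / female-hom sites.
    """

    chrom: str
    start: int
    end: int
    kind: str
    snp_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown SLR kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError("empty SLR interval")

    def as_region(self, label: str) -> Region:
        return Region(self.chrom, self.start, self.end, label=label)


def default_slr_specs() -> list[SlrSpec]:
    """One 2 Mb XY-differential SLR on a large chromosome, plus a small
    degenerate XY segment and a 200 kb Y-hemizygous segment on a second
    chromosome (window-aligned at 50 kb)."""
    return [
        SlrSpec("chr6", 30_000_000, 32_000_000, XY_DIFFERENTIAL, snp_rate=2.0),
        SlrSpec("chr2", 20_000_000, 20_100_000, XY_DIFFERENTIAL, snp_rate=0.26),
        SlrSpec("chr2", 20_100_000, 20_300_000, Y_HEMIZYGOUS),
    ]


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the TP-style cohort: 5 females, 12 weakly differentiated
    (M1) and 5 strongly differentiated (M2) males at 16.1x mean depth, 50 kb
    windows, and a planted 2 Mb XY SLR that spans ~1% of the simulated
    genome.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr2": 40_000_000, "chr6": 80_000_000}
    )
    window_size: int = 50_000
    n_females: int = 5
    n_m1: int = 12
    n_m2: int = 5
    autosomal_snp_rate: float = 5.0  # SNPs per kb
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    mean_depth: float = 16.1
    depth_dispersion: float = 0.02  # variance of the unit-mean gamma multiplier
    slr_specs: list[SlrSpec] = field(default_factory=default_slr_specs)
    m1_y_similarity: float = 0.95
    genotype_error: float = 0.001
    missing_rate: float = 0.02
    hemi_noise_floor: float = 0.0  # max female/M1 depth inside Y-hemizygous windows
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("m1_y_similarity", "genotype_error", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for spec in self.slr_specs:
            if spec.chrom not in self.chrom_lengths:
                raise ValueError(f"SLR on unknown chromosome {spec.chrom!r}")
            if spec.end > self.chrom_lengths[spec.chrom]:
                raise ValueError(
                    f"SLR {spec.chrom}:{spec.start}-{spec.end} exceeds chromosome length"
                )


@dataclass
class CohortTruth:
    """Ground truth for one simulated cohort.

    ``locus_labels`` is aligned to the emitted GenotypeMatrix rows and takes
    values "autosomal" or "xy_differential"; ``male_class`` maps male sample
    ids to "M1"/"M2".
    """

    slr_specs: list[SlrSpec]
    locus_labels: np.ndarray
    male_class: dict[str, str]
    hemizygous_regions: list[Region]

    def xy_mask(self) -> np.ndarray:
        return self.locus_labels == "xy_differential"

    def xy_regions(self) -> list[Region]:
        return [
            s.as_region("SLR_CANDIDATE") for s in self.slr_specs if s.kind == XY_DIFFERENTIAL
        ]

    def to_json(self) -> dict:
        return {
            "slr_specs": [asdict(s) for s in self.slr_specs],
            "locus_labels": self.locus_labels.tolist(),
            "male_class": self.male_class,
            "hemizygous_regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end}
                for r in self.hemizygous_regions
            ],
        }

    @classmethod
    def from_json(cls, data: dict) -> "CohortTruth":
        return cls(
            slr_specs=[SlrSpec(**s) for s in data["slr_specs"]],
            locus_labels=np.array(data["locus_labels"], dtype=object),
            male_class=dict(data["male_class"]),
            hemizygous_regions=[
                Region(r["chrom"], r["start"], r["end"], label=HEMIZYGOUS)
                for r in data["hemizygous_regions"]
            ],
        )


_BASES = np.array(list("ACGT"))


def _unique_positions(rng: np.random.Generator, start: int, end: int, rate_per_kb: float) -> np.ndarray:
    n = rng.poisson((end - start) / 1_000.0 * rate_per_kb)
    if n == 0:
        return np.empty(0, dtype=int)
    return np.unique(rng.integers(start, end, size=n))


def _in_any(chrom: str, pos: np.ndarray, specs: list[SlrSpec]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s in specs:
        if s.chrom == chrom:
            mask |= (pos >= s.start) & (pos < s.end)
    return mask


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, DepthTable, SampleSheet, CohortTruth]:
    """Draw one cohort: genotypes, window depths, sample sheet, and truth."""
    rng = np.random.default_rng(config.seed)

    female_ids = [f"F{i + 1:02d}" for i in range(config.n_females)]
    m1_ids = [f"M{i + 1:02d}" for i in range(config.n_m1)]
    m2_ids = [f"M{i + 1:02d}" for i in range(config.n_m1, config.n_m1 + config.n_m2)]
    samples = female_ids + m1_ids + m2_ids
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "sex": ["F"] * len(female_ids) + ["M"] * (len(m1_ids) + len(m2_ids)),
                "population": "SIM",
                "male_class": ["unknown"] * len(female_ids)
                + ["M1"] * len(m1_ids)
                + ["M2"] * len(m2_ids),
            }
        )
    )
    is_f = np.array([s in female_ids for s in samples])
    is_m1 = np.array([s in m1_ids for s in samples])
    is_m2 = np.array([s in m2_ids for s in samples])
    n = len(samples)

    hemi_specs = [s for s in config.slr_specs if s.kind == Y_HEMIZYGOUS]
    xy_specs = [s for s in config.slr_specs if s.kind == XY_DIFFERENTIAL]

    chroms_list: list[np.ndarray] = []
    pos_list: list[np.ndarray] = []
    label_list: list[np.ndarray] = []
    codes_list: list[np.ndarray] = []

    for chrom, length in config.chrom_lengths.items():
        # neutral background, genome-wide except Y-specific sequence
        auto_pos = _unique_positions(rng, 0, length, config.autosomal_snp_rate)
        auto_pos = auto_pos[~_in_any(chrom, auto_pos, hemi_specs)]
        a, b = config.allele_freq_beta
        p = rng.beta(a, b, size=len(auto_pos))
        auto_codes = rng.binomial(2, p[:, None], size=(len(auto_pos), n)).astype(np.int8)

        # planted XY-differential sites
        xy_pos_parts = []
        for spec in xy_specs:
            if spec.chrom == chrom:
                xy_pos_parts.append(_unique_positions(rng, spec.start, spec.end, spec.snp_rate))
        xy_pos = (
            np.unique(np.concatenate(xy_pos_parts)) if xy_pos_parts else np.empty(0, dtype=int)
        )
        female_hom = rng.choice(np.array([0, 2], dtype=np.int8), size=len(xy_pos))
        xy_codes = np.empty((len(xy_pos), n), dtype=np.int8)
        xy_codes[:, is_f] = female_hom[:, None]
        xy_codes[:, is_m2] = 1
        m1_xlike = rng.random((len(xy_pos), int(is_m1.sum()))) < config.m1_y_similarity
        xy_codes[:, is_m1] = np.where(m1_xlike, female_hom[:, None], np.int8(1))

        # XY sites displace colliding background sites
        auto_keep = ~np.isin(auto_pos, xy_pos)
        chrom_pos = np.concatenate([auto_pos[auto_keep], xy_pos])
        chrom_codes = np.concatenate([auto_codes[auto_keep], xy_codes])
        chrom_labels = np.concatenate(
            [
                np.full(int(auto_keep.sum()), "autosomal", dtype=object),
                np.full(len(xy_pos), "xy_differential", dtype=object),
            ]
        )
        order = np.argsort(chrom_pos)
        chroms_list.append(np.full(len(chrom_pos), chrom, dtype=object))
        pos_list.append(chrom_pos[order])
        label_list.append(chrom_labels[order])
        codes_list.append(chrom_codes[order])

    pos = np.concatenate(pos_list)
    codes = np.concatenate(codes_list)
    labels = np.concatenate(label_list)
    chroms = np.concatenate(chroms_list)

    ref = rng.choice(_BASES, size=len(pos))
    shift = rng.integers(1, 4, size=len(pos))
    base_idx = np.searchsorted(_BASES, ref)
    alt = _BASES[(base_idx + shift) % 4]

    # error injection, after the clean construction the truth refers to
    if config.genotype_error > 0:
        flip = rng.random(codes.shape) < config.genotype_error
        offset = rng.integers(1, 3, size=codes.shape)
        codes = np.where(flip, (codes + offset) % 3, codes).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes = np.where(miss, np.int8(-1), codes)

    loci = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    gm = GenotypeMatrix(loci, samples, codes)
    # GenotypeMatrix sorts by (chrom, pos); mirror that order for the labels
    order = (
        loci.reset_index(drop=True)
        .sort_values(["chrom", "pos"], kind="stable")
        .index.to_numpy()
    )
    labels = labels[order]

    # depth: gamma-mixed Poisson read counts per (window, sample)
    windows = make_windows(config.chrom_lengths, config.window_size)
    n_w = len(windows)
    shape = 1.0 / config.depth_dispersion
    lam = config.mean_depth * rng.gamma(shape, 1.0 / shape, size=(n_w, n))
    w_len = (windows["end"] - windows["start"]).to_numpy()[:, None]
    expected_reads = lam * w_len / config.read_length
    depth = rng.poisson(expected_reads) * config.read_length / w_len

    hemi_windows = np.zeros(n_w, dtype=bool)
    w_chrom = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy()
    w_end = windows["end"].to_numpy()
    for s in hemi_specs:
        hemi_windows |= (w_chrom == s.chrom) & (w_start < s.end) & (w_end > s.start)
    no_y = is_f | is_m1
    if hemi_windows.any():
        floor = rng.uniform(0, config.hemi_noise_floor, size=(int(hemi_windows.sum()), int(no_y.sum())))
        block = depth[hemi_windows].copy()
        block[:, no_y] = floor
        depth[hemi_windows] = block

    depth_table = DepthTable(windows, samples, depth)
    truth = CohortTruth(
        slr_specs=list(config.slr_specs),
        locus_labels=labels,
        male_class={s: ("M1" if s in m1_ids else "M2") for s in m1_ids + m2_ids},
        hemizygous_regions=[s.as_region(HEMIZYGOUS) for s in hemi_specs],
    )
    return gm, depth_table, sheet, truth


def write_cohort(
    gm: GenotypeMatrix,
    depth: DepthTable,
    sheet: SampleSheet,
    truth: CohortTruth,
    directory: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Write VCF + depth TSV + sample sheet TSV + truth JSON into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "cohort.vcf",
        "depth": directory / "depth.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.json",
    }
    _io.write_genotypes(gm, paths["vcf"], contig_lengths=contig_lengths)
    _io.write_depth(depth, paths["depth"])
    _io.write_sample_sheet(sheet, paths["samples"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return paths


def read_truth(path: str | Path) -> CohortTruth:
    with open(path) as fh:
        return CohortTruth.from_json(json.load(fh))
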