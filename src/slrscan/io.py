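"""Readers and writers for the pipeline's on-disk formats.

VCF (GT only, biallelic SNPs), TSV sample sheets, BED-like per-window depth
tables, TSV window tracks, and BED region lists.  All coordinate
conversions between the VCF 1-based convention and the internal 0-based
half-open convention happen here and in :mod:`slrscan.simulate`'s writer.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    WINDOW_COLUMNS,
    DepthTable,
    GenotypeMatrix,
    Region,
    SampleSheet,
    WindowTrack,
)

log = logging.getLogger(__name__)

_NUCLEOTIDES = {"A", "C", "G", "T"}


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read biallelic-SNP genotypes from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (a count is logged).
    Phase is ignored (``0|1`` == ``0/1``); any missing allele makes the
    call missing.  Positions are converted to 0-based.
    """
    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (GT required)")
    rows = []
    codes = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if (
            len(alts) != 1
            or rec.REF.upper() not in _NUCLEOTIDES
            or alts[0].upper() not in _NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        # per-allele codes: any missing allele (./., .|0) makes the call missing
        row = np.full(len(samples), -1, dtype=np.int8)
        for k, g in enumerate(rec.genotypes):
            alleles = g[:-1]  # last element is the phase flag
            if len(alleles) == 2 and alleles[0] >= 0 and alleles[1] >= 0:
                row[k] = alleles[0] + alleles[1]
        rows.append((rec.CHROM, rec.POS - 1, rec.REF.upper(), alts[0].upper()))
        codes.append(row)
    if n_skipped:
        log.info("%s: skipped %d multi-allelic/non-SNP records", path, n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records")
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(loci, samples, np.array(codes, dtype=np.int8))


_DEFAULT_SEX_ALIASES = {"F": "F", "M": "M"}


def read_sample_sheet(
    path: str | Path, sex_aliases: Mapping[str, str] | None = None
) -> SampleSheet:
    """Read a TSV sample sheet (columns sample_id, sex[, population, male_class]).

    ``sex_aliases`` optionally maps raw sex tokens onto "F"/"M"
    (e.g. {"female": "F"}); unmapped tokens raise.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: sample sheet must have columns {sorted(required)}")
    aliases = dict(_DEFAULT_SEX_ALIASES)
    if sex_aliases:
        aliases.update(sex_aliases)
    frame["sex"] = frame["sex"].map(lambda t: aliases.get(t, t))
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    cols = ["sample_id", "sex", "population", "male_class"]
    sheet.frame[cols].to_csv(path, sep="\t", index=False)


def read_depth(path: str | Path) -> DepthTable:
    """Read a BED-like depth table: chrom, start, end, then one column per sample."""
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns[:3]) != WINDOW_COLUMNS:
        raise ValueError(f"{path}: first three columns must be {WINDOW_COLUMNS}")
    samples = list(frame.columns[3:])
    if not samples:
        raise ValueError(f"{path}: no sample depth columns")
    depth = frame[samples].to_numpy(dtype=float)
    windows = frame[WINDOW_COLUMNS].copy()
    return DepthTable(windows, samples, depth)


def write_depth(depth: DepthTable, path: str | Path) -> None:
    frame = depth.windows[WINDOW_COLUMNS].copy()
    for j, sample in enumerate(depth.samples):
        frame[sample] = depth.depth[:, j]
    frame.to_csv(path, sep="\t", index=False)


def write_tracks(track: WindowTrack, path: str | Path) -> None:
    """Write a window track as TSV with one named column per statistic."""
    track.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tracks(path: str | Path) -> WindowTrack:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    windows = frame[WINDOW_COLUMNS].copy()
    windows["index"] = np.arange(len(windows))
    track = WindowTrack(windows)
    for name in frame.columns[3:]:
        track.add(name, frame[name].to_numpy(dtype=float))
    return track


def write_regions(regions: Sequence[Region], path: str | Path) -> None:
    """Write regions as BED (0-based half-open); empty list -> empty file."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            score = "." if r.score is None else f"{r.score:.6g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{score}\n")


def read_regions(path: str | Path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, label, score = line.rstrip("\n").split("\t")
            regions.append(
                Region(
                    chrom,
                    int(start),
                    int(end),
                    label=label,
                    score=None if score == "." else float(score),
                )
            )
    return regions


_CODE_TO_GT = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes(
    gm: GenotypeMatrix, path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT only).

    Internal 0-based positions are converted back to the VCF 1-based
    convention, making ``read_genotypes(write_genotypes(gm))`` lossless.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slrscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(gm.loci["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        chroms = gm.loci["chrom"].to_numpy()
        pos = gm.loci["pos"].to_numpy()
        ref = gm.loci["ref"].to_numpy()
        alt = gm.loci["alt"].to_numpy()
        for i in range(gm.n_loci):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in gm.codes[i])
            fh.write(f"{chroms[i]}\t{pos[i] + 1}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")
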