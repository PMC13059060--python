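"""End-to-end SLR discovery pipeline chaining every stage on one cohort.

Stages: variant filters -> window tracks (F_ST, coverage ratio, SNP
density) -> candidate-SLR calling -> locus classification -> score panels
and per-individual sex-linkage scores -> cross-region co-occurrence test ->
coverage-marker extraction -> change-point diagnostics -> structure (PCA,
NJ tree, male classes).  Results land in ``outdir`` as TSV/BED/Newick plus
a JSON summary with a provenance block (config hash, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .changepoint import ChangepointConfig, binseg_mean
from .classify import LocusClassConfig, classify_loci, sex_snp_window_counts
from .core import Region
from .filters import FilterConfig, filter_maf_missing, ld_prune
from .io import (
    read_depth,
    read_genotypes,
    read_sample_sheet,
    write_regions,
    write_tracks,
)
from .linkage import CooccurrenceConfig, build_panel, cooccurrence, sample_scores
from .markers import MarkerConfig, hemizygous_regions, male_specific_regions
from .scan import WindowScanConfig, build_track, call_slr
from .structure import assign_male_classes, ibs_distance, nj_tree, pca_genotypes

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    depth: str
    samples: str
    outdir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: WindowScanConfig = field(default_factory=WindowScanConfig)
    locus_class: LocusClassConfig = field(default_factory=LocusClassConfig)
    cooccur: CooccurrenceConfig = field(default_factory=CooccurrenceConfig)
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    changepoint: ChangepointConfig = field(default_factory=ChangepointConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        sub = {
            "filter": FilterConfig,
            "scan": WindowScanConfig,
            "locus_class": LocusClassConfig,
            "cooccur": CooccurrenceConfig,
            "marker": MarkerConfig,
            "changepoint": ChangepointConfig,
        }
        for key, value in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**(value or {}))
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _region_dict(r: Region) -> dict:
    return {"chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label, "score": r.score}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return (and write) the JSON summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("vcf", "depth", "samples"):
        path = Path(getattr(cfg, name))
        if not path.exists():
            raise FileNotFoundError(f"{name} input not found: {path}")
    log.info("pipeline config: %s", json.dumps(cfg.to_dict(), default=str))

    def stage(name):
        log.info("stage: %s", name)

    stage("load")
    gm = read_genotypes(cfg.vcf)
    depth = read_depth(cfg.depth)
    sheet = read_sample_sheet(cfg.samples)
    gm.validate_samples(sheet)
    sheet.require_both_sexes()

    stage("filter")
    gm_f = filter_maf_missing(gm, cfg.filter)

    stage("tracks")
    # When the sheet carries Y-haplotype classes, the scan contrasts the
    # females against the strongly differentiated (M2) males only: weakly
    # differentiated M1 males are largely X-like and dilute windowed F_ST.
    m2 = sheet.ids_of_class("M2")
    if m2:
        contrast_ids = sheet.ids_of_sex("F") + m2
        contrast_sheet = sheet.subset(contrast_ids)
        gm_scan = gm_f.subset_samples(contrast_ids)
        depth_scan = depth.subset_samples(contrast_ids)
    else:
        contrast_sheet, gm_scan, depth_scan = sheet, gm_f, depth
    track = build_track(gm_scan, depth_scan, contrast_sheet, cfg.scan)

    stage("call_slr")
    regions = call_slr(track, cfg.scan)
    write_regions(regions, outdir / "slr_candidates.bed")

    stage("classify")
    classes = classify_loci(gm_scan, contrast_sheet, cfg.locus_class)
    track.add("n_sex_snps", sex_snp_window_counts(classes, track.windows))
    write_tracks(track, outdir / "tracks.tsv")
    classes.to_csv(outdir / "locus_classes.tsv", sep="\t", index=False)

    stage("markers")
    male_specific = male_specific_regions(depth_scan, contrast_sheet, cfg.marker)
    hemi = hemizygous_regions(track, cfg.marker)
    write_regions(male_specific, outdir / "male_specific.bed")
    write_regions(hemi, outdir / "hemizygous.bed")

    stage("panels_scores")
    # one panel per chromosome: the best-scoring F_ST candidate, or — for a
    # degenerate SLR visible only as Y-specific coverage — the male-specific
    # region padded by two windows to pick up flanking XY loci
    best_by_chrom: dict[str, Region] = {}
    for r in regions:
        cur = best_by_chrom.get(r.chrom)
        if cur is None or (r.score or 0) * r.length > (cur.score or 0) * cur.length:
            best_by_chrom[r.chrom] = r
    pad = 2 * cfg.scan.window_size
    for r in male_specific:
        if r.chrom not in best_by_chrom:
            best_by_chrom[r.chrom] = Region(
                r.chrom, max(r.start - pad, 0), r.end + pad, label=r.label
            )
    panel_regions = sorted(best_by_chrom.values(), key=lambda r: r.length, reverse=True)[:2]
    defining = sheet.ids_of_sex("F") + (sheet.ids_of_class("M2") or sheet.ids_of_sex("M"))
    panels = [
        build_panel(gm, sheet, r, mode=cfg.locus_class.mode, defining_samples=defining)
        for r in panel_regions
    ]
    scores = [sample_scores(gm, p) for p in panels if p.n_loci > 0]
    for i, sc in enumerate(scores):
        sc.to_csv(outdir / f"scores_panel{i}.tsv", sep="\t", index=False)

    stage("cooccurrence")
    cooc = None
    if len(scores) >= 2:
        cooc = cooccurrence(scores[0], scores[1], cfg.cooccur)
        with open(outdir / "cooccurrence.json", "w") as fh:
            json.dump(
                {
                    "table": cooc.table.tolist(),
                    "fisher_p": cooc.fisher_p,
                    "spearman_rho": cooc.spearman_rho,
                    "spearman_p": cooc.spearman_p,
                    "n_discordant": cooc.n_discordant,
                    "n_excluded": cooc.n_excluded,
                },
                fh,
                indent=1,
            )

    stage("changepoint")
    cp_summary = {}
    if panel_regions:
        chrom = panel_regions[0].chrom
        m = track.windows["chrom"].to_numpy() == chrom
        series = np.nan_to_num(track["log2_cov_ratio"][m], nan=0.0)
        cp = binseg_mean(series, cfg.changepoint)
        cp_summary = {"chrom": chrom, "breakpoints": cp.breakpoints, "segment_means": cp.segment_means}

    stage("structure")
    gm_pruned = ld_prune(gm_f, cfg.filter)
    pca = pca_genotypes(gm_pruned, k=2)
    np.savetxt(
        outdir / "pca_coordinates.tsv",
        pca.coordinates,
        delimiter="\t",
        header="\t".join(["PC1", "PC2"]),
        comments="",
    )
    male_classes = {}
    newick = None
    if scores:
        male_classes = assign_male_classes(scores[0], sheet, thr=cfg.cooccur.thr_a)
        panel_gm = gm.subset_loci(panels[0].locus_mask)
        if panel_gm.n_loci >= 1 and panel_gm.n_samples >= 3:
            newick = nj_tree(ibs_distance(panel_gm))
            (outdir / "nj_tree.nwk").write_text(newick + "\n")

    summary = {
        "provenance": {
            "tool": "slrscan",
            "version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
        },
        "n_loci_input": gm.n_loci,
        "n_loci_filtered": gm_f.n_loci,
        "slr_candidates": [_region_dict(r) for r in regions],
        "panel_regions": [_region_dict(r) for r in panel_regions],
        "panel_sizes": [p.n_loci for p in panels],
        "scores": [
            {row.sample_id: (None if np.isnan(row.score) else float(row.score))
             for row in sc.itertuples()}
            for sc in scores
        ],
        "cooccurrence": None
        if cooc is None
        else {
            "table": cooc.table.tolist(),
            "fisher_p": cooc.fisher_p,
            "spearman_rho": cooc.spearman_rho,
            "spearman_p": cooc.spearman_p,
            "n_discordant": cooc.n_discordant,
        },
        "male_specific_regions": [_region_dict(r) for r in male_specific],
        "hemizygous_regions": [_region_dict(r) for r in hemi],
        "changepoint": cp_summary,
        "male_classes": male_classes,
        "pca_variance_explained": pca.variance_explained.tolist(),
        "nj_tree": newick,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
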