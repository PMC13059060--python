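"""Simulate a resequencing cohort with planted sex-linked structure.

Generates genotypes, per-window depth, a sample sheet, and the ground
truth, then writes them as VCF / TSV / JSON.  The default conditions are a
TP-style cohort: 5 females, 12 weakly differentiated (M1) and 5 strongly
differentiated (M2) males at 16.1x coverage, with a 2 Mb XY-differential
region, a small degenerate XY segment, and a 200 kb Y-hemizygous segment.
"""

from slrscan import SimConfig, simulate_cohort, write_cohort

cfg = SimConfig(seed=1)
gm, depth, sheet, truth = simulate_cohort(cfg)

print(f"samples: {len(sheet)} "
      f"({len(sheet.ids_of_sex('F'))} F, {len(sheet.ids_of_class('M1'))} M1, "
      f"{len(sheet.ids_of_class('M2'))} M2)")
print(f"loci: {gm.n_loci} ({int(truth.xy_mask().sum())} planted XY-differential)")
print(f"depth windows: {depth.n_windows} x 50 kb, mean depth "
      f"{depth.depth.mean():.1f}x")
for spec in truth.slr_specs:
    print(f"planted {spec.kind}: {spec.chrom}:{spec.start:,}-{spec.end:,}")

paths = write_cohort(gm, depth, sheet, truth, "scratch/example_cohort",
                     contig_lengths=cfg.chrom_lengths)
print("wrote:", ", ".join(str(p) for p in paths.values()))
# The XY locus count and interval list are the recovery targets for the
# scan and classification examples that follow.
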