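"""LD decay inside and outside the sex-linked region, and change-point
segmentation of a windowed track.

XY-differentiated loci segregate in strong association among males (the
Y haplotype never recombines with the X in males), so male LD inside the
SLR exceeds the autosomal background; in females the same loci are
monomorphic and contribute nothing.  Binary segmentation then locates the
mean shift the hemizygous segment leaves in the coverage-ratio track.
"""

import numpy as np

from slrscan import (
    ChangepointConfig, Region, SimConfig, binseg_mean, depth_log2_ratio,
    ld_decay, simulate_cohort,
)

gm, depth, sheet, truth = simulate_cohort(SimConfig(seed=1))
slr = truth.xy_regions()[0]

slr_window = Region(slr.chrom, slr.start, slr.start + 200_000)
auto_window = Region(slr.chrom, 0, 200_000)
male_slr = ld_decay(gm.subset_samples(sheet.ids_of_sex("M")), slr_window,
                    max_dist=50_000, bin_size=50_000)
male_auto = ld_decay(gm.subset_samples(sheet.ids_of_sex("M")), auto_window,
                     max_dist=50_000, bin_size=50_000)
print(f"male mean r2 (<=50 kb) inside SLR:  {male_slr.iloc[0]['mean_r2']:.3f}")
print(f"male mean r2 (<=50 kb) on autosome: {male_auto.iloc[0]['mean_r2']:.3f}")

# segment the chr2 coverage-ratio track (F vs M2): the hemizygous segment
# shows up as a short high-mean segment
ids = sheet.ids_of_sex("F") + sheet.ids_of_class("M2")
sub = depth.subset_samples(ids)
ratio = depth_log2_ratio(sub, sheet.subset(ids))
chr2 = (sub.windows["chrom"] == "chr2").to_numpy()
res = binseg_mean(ratio[chr2], ChangepointConfig(max_changepoints=4))
print("chr2 coverage-ratio segments (start window, mean):")
bounds = [0] + [b + 1 for b in res.breakpoints]
for lo, mu in zip(bounds, res.segment_means):
    print(f"  window {lo:4d}  mean log2(M:F) = {mu:6.2f}")
# The ~10.6-mean segment coincides with the planted hemizygous windows.
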