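"""Male-specific (Y-specific) marker regions from coverage.

Windows where every female has zero depth while the males are well covered
mark Y-specific sequence; runs of windows with log2(M:F) coverage ratio
>= 3 (an eight-fold male excess under the 0.01-pseudocount formula) mark
hemizygous regions.  Both screens run on the female-vs-M2 subset, since
only the strongly differentiated males carry the Y-specific sequence.
"""

from slrscan import (
    SimConfig, depth_log2_ratio, hemizygous_regions, male_specific_regions,
    simulate_cohort,
)
from slrscan.core import WindowTrack

gm, depth, sheet, truth = simulate_cohort(SimConfig(seed=1))

ids = sheet.ids_of_sex("F") + sheet.ids_of_class("M2")
sub = depth.subset_samples(ids)
contrast = sheet.subset(ids)

for r in male_specific_regions(sub, contrast):
    print(f"male-specific region: {r.chrom}:{r.start:,}-{r.end:,} "
          f"({r.length // 1000} kb; candidate PCR-marker source)")

track = WindowTrack(sub.windows)
track.add("log2_cov_ratio", depth_log2_ratio(sub, contrast))
for r in hemizygous_regions(track):
    print(f"hemizygous region:    {r.chrom}:{r.start:,}-{r.end:,} "
          f"(mean log2 ratio {r.score:.1f})")

(hemi,) = truth.hemizygous_regions
print(f"planted segment:      {hemi.chrom}:{hemi.start:,}-{hemi.end:,}")
# Both screens should report exactly the planted 200 kb segment; the ~10.6
# log2 ratio is the zero-female-coverage signature of hemizygous sequence.
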