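"""Cohort structure: PCA of SLR genotypes, an NJ tree of allele-sharing
distances, and M1/M2 male-class assignment.

PCA on SLR SNPs separates the strongly differentiated (M2) males from the
female-like cluster containing the females and the weakly differentiated
(M1) males; the score rule (sex-linkage score >= 0.6 -> M2) reproduces the
same split.
"""

import numpy as np

from slrscan import (
    SimConfig, assign_male_classes, build_panel, ibs_distance, nj_tree,
    pca_genotypes, sample_scores, simulate_cohort,
)

gm, depth, sheet, truth = simulate_cohort(SimConfig(seed=1))
slr = truth.xy_regions()[0]
gm_slr = gm.subset_loci(gm.region_mask(slr))

pca = pca_genotypes(gm_slr, k=2)
pc1 = dict(zip(pca.samples, pca.coordinates[:, 0]))
for group, ids in [("F", sheet.ids_of_sex("F")),
                   ("M1", sheet.ids_of_class("M1")),
                   ("M2", sheet.ids_of_class("M2"))]:
    vals = [pc1[s] for s in ids]
    print(f"PC1 {group}: mean {np.mean(vals):8.1f} (n={len(vals)})")
print(f"PC1 explains {pca.variance_explained[0] * 100:.0f}% of variance")

panel = build_panel(gm, sheet, slr)
scores = sample_scores(gm, panel)
classes = assign_male_classes(scores, sheet, thr=0.6)
correct = sum(classes[m] == truth.male_class[m] for m in classes)
print(f"male classes recovered: {correct}/{len(classes)}")

# NJ tree on the panel loci: M2 males form a distinct cluster, females a
# second one, and M1 males sit with the females
newick = nj_tree(ibs_distance(gm.subset_loci(panel.locus_mask)))
print("NJ tree (Newick):")
print(newick)
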