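import io

import numpy as np
import pandas as pd
import pytest

from slrscan import (
    assign_male_classes,
    assign_male_classes_pca,
    build_panel,
    ibs_distance,
    nj_tree,
    pca_genotypes,
    sample_scores,
)
from slrscan.structure import _dosage_standardized

from conftest import make_gm, make_sheet


class TestPca:
    def test_duplicated_sample_pairs_symmetry(self):
        # two pairs of identical samples, maximally different between pairs
        codes = np.array([[0, 0, 2, 2]] * 20, dtype=np.int8)
        gm = make_gm(codes)
        res = pca_genotypes(gm, k=1)
        c = res.coordinates[:, 0]
        assert c[0] == pytest.approx(c[1], abs=1e-9)
        assert c[2] == pytest.approx(c[3], abs=1e-9)
        assert abs(c[0] - c[2]) > 1.0

    def test_monomorphic_loci_contribute_nothing(self):
        rng = np.random.default_rng(1)
        poly = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        mono = np.concatenate([poly, np.zeros((5, 6), np.int8), np.full((5, 6), 2, np.int8)])
        a = pca_genotypes(make_gm(poly), k=2)
        b = pca_genotypes(make_gm(mono), k=2)
        np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        """Coordinates match a direct eigendecomposition of Z Z^T."""
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(12, 5)).astype(np.int8)
        gm = make_gm(codes)
        res = pca_genotypes(gm, k=3)
        z = _dosage_standardized(gm)
        evals, evecs = np.linalg.eigh(z @ z.T)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            expect = evecs[:, j] * np.sqrt(evals[j])
            got = res.coordinates[:, j]
            # same axis up to sign
            assert min(
                np.abs(got - expect).max(), np.abs(got + expect).max()
            ) < 1e-10
            assert res.variance_explained[j] == pytest.approx(
                evals[j] / evals.sum(), abs=1e-12
            )

    def test_invariant_to_locus_order(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        a = pca_genotypes(make_gm(codes), k=2)
        perm = rng.permutation(30)
        b = pca_genotypes(make_gm(codes[perm]), k=2)
        for j in range(2):
            assert min(
                np.abs(a.coordinates[:, j] - b.coordinates[:, j]).max(),
                np.abs(a.coordinates[:, j] + b.coordinates[:, j]).max(),
            ) < 1e-9


class TestIbsDistance:
    def test_identical_samples(self):
        gm = make_gm([[1, 1], [0, 0], [2, 2]])
        d = ibs_distance(gm)
        assert d.iloc[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        gm = make_gm([[0, 2], [0, 2], [2, 0]])
        assert ibs_distance(gm).iloc[0, 1] == 1.0

    def test_half_shared(self):
        gm = make_gm([[0, 1]])
        assert ibs_distance(gm).iloc[0, 1] == 0.5

    def test_pairwise_deletion_and_error(self):
        gm = make_gm([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="no called locus"):
            ibs_distance(gm)


def _paths_from_newick(newick):
    """Patristic distances via scikit-bio (independent tree parser)."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    return tree.tip_tip_distances()


class TestNjTree:
    ADDITIVE = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"),
        columns=list("ABCD"),
        dtype=float,
    )

    def test_three_taxa_three_point_formulas(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        newick = nj_tree(d)
        dm = _paths_from_newick(newick)
        got = dm.filter(["A", "B", "C"]).data
        np.testing.assert_allclose(got, d.to_numpy(), atol=1e-9)

    def test_additive_four_taxon_tree_recovered_exactly(self):
        """NJ is exact on additive matrices: the generating tree
        ((A:1,B:2):1,(C:3,D:4)) is recovered with its branch lengths."""
        newick = nj_tree(self.ADDITIVE)
        dm = _paths_from_newick(newick)
        ids = list(dm.ids)
        got = pd.DataFrame(dm.data, index=ids, columns=ids).loc[list("ABCD"), list("ABCD")]
        np.testing.assert_allclose(got.to_numpy(), self.ADDITIVE.to_numpy(), atol=1e-9)
        # AB|CD split: A and B are siblings
        assert "(A:" in newick.replace(" ", "") or "A:1" in newick

    def test_matches_skbio_nj_on_additive_matrix(self):
        """Independent cross-check: scikit-bio's NJ yields the same
        path-length matrix on an additive input."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        dm = DistanceMatrix(self.ADDITIVE.to_numpy(), ids=list("ABCD"))
        ref = skbio_nj(dm).tip_tip_distances()
        ids = list(ref.ids)
        ref_frame = pd.DataFrame(ref.data, index=ids, columns=ids).loc[
            list("ABCD"), list("ABCD")
        ]
        ours = _paths_from_newick(nj_tree(self.ADDITIVE))
        ids2 = list(ours.ids)
        ours_frame = pd.DataFrame(ours.data, index=ids2, columns=ids2).loc[
            list("ABCD"), list("ABCD")
        ]
        np.testing.assert_allclose(
            ours_frame.to_numpy(), ref_frame.to_numpy(), atol=1e-9
        )

    def test_taxon_order_permutation_isomorphic(self):
        perm = ["C", "A", "D", "B"]
        newick = nj_tree(self.ADDITIVE.loc[perm, perm])
        dm = _paths_from_newick(newick)
        ids = list(dm.ids)
        got = pd.DataFrame(dm.data, index=ids, columns=ids).loc[list("ABCD"), list("ABCD")]
        np.testing.assert_allclose(got.to_numpy(), self.ADDITIVE.to_numpy(), atol=1e-9)

    def test_too_few_taxa_errors(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(d)


class TestMaleClasses:
    def test_score_rule_on_simulated_cohort(self, small_cohort):
        gm, _, sheet, truth = small_cohort
        panel = build_panel(gm, sheet, truth.xy_regions()[0])
        scores = sample_scores(gm, panel)
        got = assign_male_classes(scores, sheet, thr=0.6)
        assert got == truth.male_class

    def test_all_zero_scores_are_m1(self):
        sheet = make_sheet("FFMMM", samples=list("ABCDE"))
        scores = pd.DataFrame(
            {"sample_id": list("ABCDE"), "n_called": 5, "n_het": 0, "score": 0.0}
        )
        got = assign_male_classes(scores, sheet)
        assert got == {"C": "M1", "D": "M1", "E": "M1"}

    def test_uniform_high_scores_are_m2(self):
        sheet = make_sheet("FFMMM", samples=list("ABCDE"))
        scores = pd.DataFrame(
            {"sample_id": list("ABCDE"), "n_called": 5, "n_het": 5, "score": 0.95}
        )
        got = assign_male_classes(scores, sheet)
        assert set(got.values()) == {"M2"}

    def test_single_male_is_unknown(self):
        sheet = make_sheet("FFM", samples=list("ABC"))
        scores = pd.DataFrame(
            {"sample_id": list("ABC"), "n_called": 5, "n_het": 5, "score": 1.0}
        )
        assert assign_male_classes(scores, sheet) == {"C": "unknown"}

    def test_pca_rule_on_simulated_cohort(self, small_cohort):
        gm, _, sheet, truth = small_cohort
        slr = truth.xy_regions()[0]
        gm_slr = gm.subset_loci(gm.region_mask(slr))
        got = assign_male_classes_pca(gm_slr, sheet)
        assert got == truth.male_class
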