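import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slrscan import LocusClassConfig, classify_loci, heatmap_matrix, sex_snp_window_counts
from slrscan.classify import NONE, XY_LIKE, XY_STRICT, ZW_STRICT
from slrscan.core import make_windows

from conftest import make_gm, make_sheet


SHEET_5F5M = make_sheet("FFFFFMMMMM")


def _labels(codes, sheet=SHEET_5F5M, **cfg):
    gm = make_gm(codes)
    return classify_loci(gm, sheet, LocusClassConfig(**cfg))["label"].tolist()


class TestClassifyLocus:
    def test_strict_pattern(self):
        # 5F all 0/0, 5M all 0/1 -> strict (and therefore XY-like)
        assert _labels([[0] * 5 + [1] * 5]) == [XY_STRICT]
        assert _labels([[0] * 5 + [1] * 5], mode="strict") == [XY_STRICT]

    def test_relaxed_enrichment_threshold(self):
        # males {het x3, hom x2}: het fraction 0.6 >= 0.5 -> XY-like, not strict
        codes = [[0] * 5 + [1, 1, 1, 0, 0]]
        assert _labels(codes) == [XY_LIKE]
        assert _labels(codes, mode="strict") == [NONE]
        # raising the cutoff above 0.6 drops it
        assert _labels(codes, male_het_enrichment=0.7) == [NONE]

    def test_females_not_fixed(self):
        codes = [[0, 1, 0, 0, 0] + [1] * 5]
        assert _labels(codes) == [NONE]

    def test_females_fixed_alt_counts(self):
        codes = [[2] * 5 + [1] * 5]
        assert _labels(codes) == [XY_STRICT]

    def test_zw_mode_swaps_sexes(self):
        codes = [[1] * 5 + [0] * 5]
        assert _labels(codes, mode="zw_strict") == [ZW_STRICT]
        assert _labels(codes) == [NONE]

    def test_min_called_per_sex(self):
        # only 2 called females < 3 -> none
        codes = [[0, 0, -1, -1, -1] + [1] * 5]
        assert _labels(codes) == [NONE]
        assert _labels(codes, min_called_per_sex=2) == [XY_STRICT]

    @settings(deadline=None, max_examples=50)
    @given(
        codes=st.lists(
            st.lists(st.sampled_from([0, 1, 2, -1]), min_size=10, max_size=10),
            min_size=1,
            max_size=4,
        )
    )
    def test_ref_alt_flip_invariance(self, codes):
        """Relabelling ref<->alt (dosage g -> 2-g) never changes labels."""
        arr = np.array(codes, dtype=np.int8)
        flipped = np.where(arr >= 0, 2 - arr, arr).astype(np.int8)
        a = classify_loci(make_gm(arr), SHEET_5F5M)["label"]
        b = classify_loci(make_gm(flipped), SHEET_5F5M)["label"]
        assert a.tolist() == b.tolist()

    @settings(deadline=None, max_examples=30)
    @given(
        codes=st.lists(
            st.lists(st.sampled_from([0, 1, 2, -1]), min_size=10, max_size=10),
            min_size=1,
            max_size=4,
        ),
        lo=st.floats(0.1, 0.5),
        hi=st.floats(0.5, 1.0),
    )
    def test_monotone_in_enrichment_cutoff(self, codes, lo, hi):
        """Raising male_het_enrichment never adds XY-like loci."""
        arr = np.array(codes, dtype=np.int8)
        low = classify_loci(make_gm(arr), SHEET_5F5M, LocusClassConfig(male_het_enrichment=min(lo, hi)))
        high = classify_loci(make_gm(arr), SHEET_5F5M, LocusClassConfig(male_het_enrichment=max(lo, hi)))
        added = (high["label"] != NONE) & (low["label"] == NONE)
        assert not added.any()


def test_strict_mode_recovers_planted_loci(clean_cohort):
    """Error-free cohort, F-vs-M2 contrast: every planted XY locus is
    classified strict (recall 1), and any extra strict call is a background
    locus that genuinely exhibits the XY pattern by chance in this finite
    cohort (verified against the raw genotypes), so the classifier itself
    is exact with respect to its rule."""
    gm, _, sheet, truth = clean_cohort
    ids = sheet.ids_of_sex("F") + sheet.ids_of_class("M2")
    sub = gm.subset_samples(ids)
    classes = classify_loci(sub, sheet.subset(ids), LocusClassConfig(mode="strict"))
    got = (classes["label"] == XY_STRICT).to_numpy()
    planted = truth.xy_mask()
    assert not np.any(planted & ~got)  # recall = 1
    extras = np.flatnonzero(got & ~planted)
    assert len(extras) < 0.001 * gm.n_loci
    f_idx = sub.sample_indices(sheet.ids_of_sex("F"))
    m_idx = sub.sample_indices(sheet.ids_of_class("M2"))
    for i in extras:
        f = sub.codes[i, f_idx]
        m = sub.codes[i, m_idx]
        assert np.all(m == 1)
        assert np.all(f == f[0]) and f[0] in (0, 2)


def test_sex_snp_window_counts(clean_cohort):
    """Window counts equal an independent per-window tally of the
    classified loci."""
    gm, depth, sheet, truth = clean_cohort
    ids = sheet.ids_of_sex("F") + sheet.ids_of_class("M2")
    classes = classify_loci(
        gm.subset_samples(ids), sheet.subset(ids), LocusClassConfig(mode="strict")
    )
    counts = sex_snp_window_counts(classes, depth.windows)
    labelled = (classes["label"] != NONE).to_numpy()
    from slrscan.core import assign_windows

    idx = assign_windows(
        depth.windows,
        classes["chrom"].to_numpy()[labelled],
        classes["pos"].to_numpy()[labelled],
    )
    expected = np.bincount(idx, minlength=len(depth.windows))
    np.testing.assert_array_equal(counts, expected)
    # planted loci are a per-window lower bound
    xy_idx = assign_windows(
        depth.windows,
        gm.loci["chrom"].to_numpy()[truth.xy_mask()],
        gm.loci["pos"].to_numpy()[truth.xy_mask()],
    )
    planted_counts = np.bincount(xy_idx, minlength=len(depth.windows))
    assert np.all(counts >= planted_counts)


def test_sex_snp_counts_zero_without_classified_loci():
    gm = make_gm([[0, 1, 0, 1]] * 3)
    classes = classify_loci(gm, make_sheet("FFMM"), LocusClassConfig(min_called_per_sex=2))
    windows = make_windows({"chr1": 10_000}, 1000)
    assert sex_snp_window_counts(classes, windows).sum() == 0


class TestHeatmapMatrix:
    def test_small_panel_kept_whole(self, small_cohort):
        gm, _, sheet, truth = small_cohort
        mask = np.zeros(gm.n_loci, dtype=bool)
        mask[:100] = True
        matrix, loci, order = heatmap_matrix(gm, mask, sheet)
        assert len(matrix) == 100

    def test_subsample_size_and_determinism(self, small_cohort):
        gm, _, sheet, _ = small_cohort
        mask = np.ones(gm.n_loci, dtype=bool)
        m1, l1, _ = heatmap_matrix(gm, mask, sheet, n_subsample=5000, seed=42)
        m2, l2, _ = heatmap_matrix(gm, mask, sheet, n_subsample=5000, seed=42)
        assert len(m1) == 5000
        assert l1.equals(l2) and m1.equals(m2)
        m3, l3, _ = heatmap_matrix(gm, mask, sheet, n_subsample=5000, seed=43)
        assert not l1.equals(l3)

    def test_column_order_f_m1_m2(self, small_cohort):
        gm, _, sheet, _ = small_cohort
        mask = np.zeros(gm.n_loci, dtype=bool)
        mask[:10] = True
        _, _, order = heatmap_matrix(gm, mask, sheet)
        expected = (
            sheet.ids_of_sex("F") + sheet.ids_of_class("M1") + sheet.ids_of_class("M2")
        )
        assert order == expected
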