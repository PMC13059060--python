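import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from slrscan import (
    CooccurrenceConfig,
    Region,
    build_panel,
    cooccurrence,
    fisher_exact_2x2,
    sample_scores,
    spearman,
)

from conftest import make_gm, make_sheet


class TestFisherExact:
    def test_perfect_concordance_table(self):
        """5 concordant-high vs 17 concordant-low: the observed table is the
        unique most extreme one given its margins, p = 1 / C(22, 5)."""
        p = fisher_exact_2x2([[5, 0], [0, 17]])
        assert p == pytest.approx(1.0 / comb(22, 5, exact=True), rel=1e-9)
        assert p == pytest.approx(3.80e-5, abs=0.005e-5)

    def test_tiny_tables(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_all_zero_table(self):
        assert fisher_exact_2x2([[0, 0], [0, 0]]) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(cells=st.tuples(*[st.integers(0, 12) for _ in range(4)]))
    def test_invariant_under_transpose_and_swaps(self, cells):
        t = np.array(cells).reshape(2, 2)
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p, rel=1e-9)


def _midrank(v):
    """Rank oracle by explicit counting (average ranks for ties)."""
    v = list(v)
    return [
        1 + sum(1 for u in v if u < x) + (sum(1 for u in v if u == x) - 1) / 2
        for x in v
    ]


def _pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestSpearman:
    def test_monotone_identity(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_small_example(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)  # 1 - 6*6/24

    def test_ties_use_midranks(self):
        rho, _ = spearman([1, 1, 2], [1, 2, 3])
        assert rho == pytest.approx(1.5 / np.sqrt(3))  # ~0.8660

    def test_matches_rank_oracle_for_small_n(self):
        """Mid-rank Pearson oracle over random vectors, n <= 6."""
        rng = np.random.default_rng(8)
        for n in range(3, 7):
            for _ in range(40):
                x = rng.integers(0, 4, n)
                y = rng.integers(0, 4, n)
                rx, ry = _midrank(x), _midrank(y)
                if len(set(rx)) == 1 or len(set(ry)) == 1:
                    continue
                rho, _ = spearman(x, y)
                assert rho == pytest.approx(_pearson(rx, ry), abs=1e-12)

    def test_paper_scale_t_approximation(self):
        """rho = 0.725 at n = 22 yields p ~ 1.3e-4 under the t-approximation."""
        rho = 0.725
        n = 22
        from scipy import stats

        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(t, df=n - 2)
        assert p == pytest.approx(1.37e-4, rel=0.05)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])


def _xy_gm_and_sheet():
    """5F + 3 M2 defining cohort plus 2 extra males, 10 panel-able loci."""
    samples = [f"F{i}" for i in range(5)] + [f"M{i}" for i in range(5)]
    sheet = make_sheet(
        "FFFFFMMMMM",
        samples=samples,
        male_classes=["unknown"] * 5 + ["M1", "M1", "M2", "M2", "M2"],
    )
    codes = []
    for _ in range(8):  # XY loci: females hom-ref, M2 het, M1 hom-ref
        codes.append([0] * 5 + [0, 0, 1, 1, 1])
    codes.append([0, 1, 0, 1, 0] * 2)  # noise locus, females not fixed
    codes.append([2] * 10)  # monomorphic alt
    return make_gm(codes, samples=samples), sheet


class TestPanelsAndScores:
    def test_panel_from_defining_contrast(self):
        gm, sheet = _xy_gm_and_sheet()
        region = Region("chr1", 0, 100_000)
        panel = build_panel(gm, sheet, region)
        assert panel.n_loci == 8
        assert panel.defining_samples == [f"F{i}" for i in range(5)] + ["M2", "M3", "M4"]

    def test_empty_region_panel(self):
        gm, sheet = _xy_gm_and_sheet()
        panel = build_panel(gm, sheet, Region("chr9", 0, 1000))
        assert panel.n_loci == 0

    def test_panel_ignores_non_defining_genotypes(self):
        gm, sheet = _xy_gm_and_sheet()
        codes = gm.codes.copy()
        codes[:, 5] = 1  # scramble a non-defining M1 male
        gm2 = make_gm(codes, samples=gm.samples)
        region = Region("chr1", 0, 100_000)
        assert build_panel(gm, sheet, region).loci.equals(
            build_panel(gm2, sheet, region).loci
        )

    def test_score_arithmetic(self):
        gm, sheet = _xy_gm_and_sheet()
        panel = build_panel(gm, sheet, Region("chr1", 0, 100_000))
        codes = gm.codes.copy()
        codes[panel.locus_mask, 5] = [1, 1] + [0] * 6  # M0: 8 called, 2 het
        scores = sample_scores(make_gm(codes, samples=gm.samples), panel)
        row = scores.set_index("sample_id").loc["M0"]
        assert row["n_called"] == 8 and row["n_het"] == 2
        assert row["score"] == pytest.approx(0.25)

    def test_all_missing_sample_is_undefined(self):
        gm, sheet = _xy_gm_and_sheet()
        panel = build_panel(gm, sheet, Region("chr1", 0, 100_000))
        codes = gm.codes.copy()
        codes[panel.locus_mask, 9] = -1
        scores = sample_scores(make_gm(codes, samples=gm.samples), panel)
        assert np.isnan(scores.set_index("sample_id").loc["M4", "score"])

    def test_defining_females_score_exactly_zero(self, small_cohort):
        """Structural identity: panel loci force defining females to be
        fixed homozygous, so their heterozygote proportion is exactly 0."""
        gm, _, sheet, truth = small_cohort
        panel = build_panel(gm, sheet, truth.xy_regions()[0])
        assert panel.n_loci > 0
        scores = sample_scores(gm, panel).set_index("sample_id")
        for f in sheet.ids_of_sex("F"):
            assert scores.loc[f, "score"] == 0.0


class TestCooccurrence:
    def _scores(self, values):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(values))],
                "n_called": 10,
                "n_het": 0,
                "score": values,
            }
        )

    def test_perfect_separation_matches_study_statistics(self):
        """5 concordant-high + 17 concordant-low individuals: Fisher exact
        p = 3.80e-5 and no discordant individuals."""
        a = self._scores([0.9] * 5 + [0.05] * 12 + [0.0] * 5)
        b = self._scores([0.8] * 5 + [0.04] * 12 + [0.0] * 5)
        res = cooccurrence(a, b, CooccurrenceConfig(thr_a=0.6, thr_b=0.3))
        assert res.table.tolist() == [[5, 0], [0, 17]]
        assert res.fisher_p == pytest.approx(3.80e-5, abs=0.005e-5)
        assert res.n_discordant == 0

    def test_all_low_is_null(self):
        a = self._scores([0.1] * 8)
        b = self._scores([0.2] * 8)
        res = cooccurrence(a, b)
        assert res.fisher_p == 1.0

    def test_identical_scores_have_rho_one(self):
        a = self._scores([0.9, 0.5, 0.1, 0.7, 0.3])
        res = cooccurrence(a, a.copy())
        assert res.spearman_rho == pytest.approx(1.0)

    def test_undefined_scores_excluded_pairwise(self):
        a = self._scores([0.9, np.nan, 0.1, 0.7])
        b = self._scores([0.8, 0.5, 0.2, np.nan])
        res = cooccurrence(a, b)
        assert res.n_excluded == 2
        assert res.table.sum() == 2
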