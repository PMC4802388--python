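"""Clinical-table statistics and the 2x2 mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lobeconn.stats import (
    chi_square_2x2,
    edge_keep_mask,
    edge_screen,
    exclude_damaged,
    false_positive_adjust,
    mixed_anova_2x2,
    pearson_corr,
    t_from_summary,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = two_sample_t(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_summary_and_raw_paths_agree(self, rng):
        x = rng.normal(1, 2, 20)
        y = rng.normal(0.5, 1.5, 12)
        for variant in ("pooled", "welch"):
            raw = two_sample_t(x, y, variant)
            summ = t_from_summary(
                x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), variant
            )
            assert raw[0] == pytest.approx(summ[0], abs=1e-10)
            assert raw[2] == pytest.approx(summ[2], abs=1e-10)

    def test_zero_variance_flagged_infinite(self):
        t, _, p = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and t < 0 and p == 0.0

    def test_equal_summary_means_give_zero_t(self):
        t, _, _ = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 8)
        assert t == 0.0

    def test_cohort_demographics_reproduce_printed_p_values(self):
        # preoperative age, postoperative age, postoperative duration
        assert round(t_from_summary(24.52, 8.32, 23, 26.64, 9.68, 14)[2], 2) == 0.48
        assert round(t_from_summary(23.50, 7.76, 14, 27.00, 11.59, 10)[2], 2) == 0.38
        assert round(t_from_summary(14.07, 6.72, 14, 11.23, 5.76, 10)[2], 2) == 0.29

    def test_lacuna_volume_welch(self):
        t, _, p = t_from_summary(5.14, 1.66, 14, 4.84, 1.99, 10, variant="welch")
        assert round(t, 2) == 0.39
        assert round(p, 2) == 0.70


class TestChiSquare:
    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_postoperative_sex_table(self):
        _, p = chi_square_2x2([[9, 5], [5, 5]])
        assert round(p, 2) == 0.48

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            t = rng.integers(1, 30, size=(2, 2)).astype(float)
            chi2, _ = chi_square_2x2(t)
            n = t.sum()
            a, b, c, d = t.ravel()
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(closed, rel=1e-12)

    def test_yates_correction_shrinks_statistic(self):
        plain, _ = chi_square_2x2([[15, 8], [6, 8]])
        corrected, _ = chi_square_2x2([[15, 8], [6, 8]], yates=True)
        assert corrected < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestPearson:
    def test_exact_linear(self):
        r, p = pearson_corr([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.standard_normal(5), rng.standard_normal(5)
        r, _ = pearson_corr(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_independent_large_sample_near_zero(self, rng):
        r, _ = pearson_corr(rng.standard_normal(5000), rng.standard_normal(5000))
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFalsePositiveAdjust:
    @pytest.mark.parametrize("n,expected", [(96, 1 / 96), (1, 1.0), (474, 1 / 474), (110, 1 / 110)])
    def test_threshold(self, n, expected):
        assert false_positive_adjust(n) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            false_positive_adjust(0)


class TestMixedAnova:
    def test_hand_worked_example(self):
        # SF pairs {(1,3),(2,3)}, NSF pairs {(3,3),(2,3)}: difference scores
        # {2,1} vs {0,1} -> pooled t = sqrt(2), F(1,2) = 2, p ~ 0.293
        res = mixed_anova_2x2([1, 2], [3, 3], [3, 2], [3, 3])
        assert res.f_interaction[0] == pytest.approx(2.0, abs=1e-12)
        assert res.p_interaction[0] == pytest.approx(0.29289, abs=1e-4)
        assert res.df_within == (1, 2)

    @pytest.mark.parametrize("seed", range(30))
    def test_interaction_equals_squared_difference_score_t(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 20)), int(rng.integers(3, 20))
        sf_pre, sf_post = rng.standard_normal((2, n1, 4))
        nsf_pre, nsf_post = rng.standard_normal((2, n2, 4))
        res = mixed_anova_2x2(sf_pre, sf_post, nsf_pre, nsf_post)
        t = sps.ttest_ind(sf_post - sf_pre, nsf_post - nsf_pre, axis=0)
        assert np.allclose(res.f_interaction, t.statistic**2, rtol=1e-8)
        assert np.allclose(res.p_interaction, t.pvalue, rtol=1e-8)

    def test_location_invariance(self, rng):
        cells = rng.standard_normal((4, 6, 3))
        a = mixed_anova_2x2(*cells)
        b = mixed_anova_2x2(*(c + 17.3 for c in cells))
        for name in ("f_interaction", "f_outcome", "f_treatment"):
            assert np.allclose(getattr(a, name), getattr(b, name), rtol=1e-9)

    def test_matches_pingouin_on_unbalanced_data(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n1, n2 = 8, 5
        sf_pre, sf_post = rng.standard_normal((2, n1))
        nsf_pre, nsf_post = rng.standard_normal((2, n2))
        res = mixed_anova_2x2(sf_pre, sf_post, nsf_pre, nsf_post)
        rows = []
        for g, pre, post, off in (("SF", sf_pre, sf_post, 0), ("NSF", nsf_pre, nsf_post, n1)):
            for k in range(len(pre)):
                rows.append({"subject": off + k, "group": g, "time": "pre", "y": pre[k]})
                rows.append({"subject": off + k, "group": g, "time": "post", "y": post[k]})
        df = pd.DataFrame(rows)
        pg = pingouin.mixed_anova(df, dv="y", within="time", subject="subject", between="group")
        pg = pg.set_index("Source")
        assert res.f_interaction[0] == pytest.approx(pg.loc["Interaction", "F"], rel=1e-6)
        assert res.f_outcome[0] == pytest.approx(pg.loc["group", "F"], rel=1e-6)

    def test_unpaired_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="unpaired"):
            mixed_anova_2x2(rng.standard_normal((4, 2)), rng.standard_normal((3, 2)),
                            rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))

    def test_cell_means_reported(self):
        res = mixed_anova_2x2([1, 2], [3, 3], [3, 2], [3, 3])
        assert res.cell_means["SF_pre"][0] == pytest.approx(1.5)
        assert res.cell_means["NSF_post"][0] == pytest.approx(3.0)


class TestEdgeScreen:
    def test_pure_noise_around_zero_mostly_dropped(self, rng):
        data = {k: rng.standard_normal((10, 200)) for k in ("a", "b", "c", "d")}
        mask = edge_screen(data, alpha=0.05)
        # under the null each feature passes one of four tests with p ~ 0.185
        assert mask.mean() < 0.35

    def test_strong_feature_retained(self, rng):
        a = rng.standard_normal((8, 3)) * 0.01
        a[:, 1] += 1.0
        mask = edge_screen({"only": a})
        assert mask[1] and not mask[0]

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            edge_screen({"a": np.zeros((1, 4))})


class TestExcludeDamaged:
    def test_no_lesions_keeps_everything(self):
        assert exclude_damaged(np.zeros((5, 10))).all()

    def test_study_sized_exclusion(self, rng):
        # 14 of 110 regions damaged somewhere in the cohort -> 96 remain
        fractions = np.zeros((24, 110))
        damaged = rng.choice(110, size=14, replace=False)
        for k, roi in enumerate(damaged):
            fractions[k % 24, roi] = rng.uniform(0.1, 1.0)
        keep = exclude_damaged(fractions)
        assert keep.sum() == 96
        assert not keep[damaged].any()

    def test_edge_mask_drops_incident_edges(self):
        keep = np.array([True, False, True, True])
        mask = edge_keep_mask(keep)
        # pairs in order: 01 02 03 12 13 23
        assert list(mask) == [False, True, True, False, False, True]
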