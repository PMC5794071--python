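"""Wilks-lambda MANOVA: dispersion identities, oracle equivalence,
Bartlett transform, screening, tallies, and the univariate matching tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from roifuse import (
    bartlett_chi2_p,
    dispersion_matrices,
    pearson_chi2_2x2,
    pooled_t_test,
    screen_rois,
    tally_best_measure,
    wilks_lambda,
    wilks_test,
)
from roifuse.features import FusionFeatureSet


def wilks_oracle(X, groups):
    """Independent Wilks statistic from statsmodels' MANOVA machinery."""
    from statsmodels.multivariate.manova import MANOVA

    df = pd.DataFrame(X, columns=[f"y{i}" for i in range(X.shape[1])])
    df["g"] = groups
    formula = " + ".join(df.columns[:-1]) + " ~ C(g)"
    res = MANOVA.from_formula(formula, data=df).mv_test()
    tab = res.results["C(g)"]["stat"]
    return float(tab.loc["Wilks' lambda", "Value"])


class TestDispersion:
    def test_identical_group_means_give_zero_between(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((8, 3))
        b = a[::-1]  # same rows, same mean
        X = np.vstack([a, b])
        groups = np.r_[np.zeros(8), np.ones(8)]
        d = dispersion_matrices(X, groups)
        assert np.allclose(d.B, 0.0, atol=1e-10)
        assert np.allclose(d.T, d.W)
        assert wilks_lambda(d) == pytest.approx(1.0)

    def test_univariate_matches_scalar_sums_of_squares(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(12)
        groups = np.r_[np.zeros(5), np.ones(7)]
        d = dispersion_matrices(x, groups)
        ssw = sum(
            ((x[groups == g] - x[groups == g].mean()) ** 2).sum() for g in (0, 1)
        )
        sst = ((x - x.mean()) ** 2).sum()
        assert d.W[0, 0] == pytest.approx(ssw, rel=1e-12)
        assert d.T[0, 0] == pytest.approx(sst, rel=1e-12)

    def test_total_equals_within_plus_between(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 3))
        groups = rng.integers(0, 2, 12)
        groups[:2] = [0, 1]  # both groups present
        d = dispersion_matrices(X, groups)
        assert np.allclose(d.T, d.W + d.B, atol=1e-10)

    def test_empty_measurement_vector_rejected(self):
        with pytest.raises(ValueError, match="m = 0"):
            dispersion_matrices(np.empty((6, 0)), np.r_[0, 0, 0, 1, 1, 1])


class TestWilks:
    def test_univariate_closed_form_equivalence(self):
        # for m=1, G=2: lambda = 1/(1 + t^2/(n-2)) with the pooled t
        rng = np.random.default_rng(3)
        x = np.r_[rng.standard_normal(10) + 0.8, rng.standard_normal(14)]
        groups = np.r_[np.zeros(10), np.ones(14)]
        lam = wilks_lambda(dispersion_matrices(x, groups))
        t, df, _ = pooled_t_test(x[:10], x[10:])
        assert lam == pytest.approx(1.0 / (1.0 + t**2 / df), rel=1e-12)

    @pytest.mark.parametrize("seed,G,m", [(0, 2, 4), (1, 2, 2), (2, 3, 4), (3, 3, 5)])
    def test_matches_statsmodels_oracle(self, seed, G, m):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, m))
        groups = np.repeat(np.arange(G), [40 // G] * (G - 1) + [40 - (G - 1) * (40 // G)])
        lam = wilks_lambda(dispersion_matrices(X, groups))
        assert lam == pytest.approx(wilks_oracle(X, groups), abs=1e-8)

    def test_singular_total_matrix_directs_to_ridge_path(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        X = np.column_stack([X, X[:, 0]])  # duplicated column: T singular
        groups = np.r_[np.zeros(15), np.ones(15)]
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            wilks_lambda(dispersion_matrices(X, groups))
        lam, chi2, df, p = wilks_test(X, groups, ridge=True)
        assert 0 < lam <= 1

    def test_chi2_monotone_decreasing_in_lambda(self):
        chis = [bartlett_chi2_p(lam, 50, 2, 3)[0] for lam in (0.9, 0.5, 0.2)]
        assert chis[0] < chis[1] < chis[2]


class TestBartlett:
    def test_lambda_one_gives_zero_chi2_p_one(self):
        chi2, df, p = bartlett_chi2_p(1.0, 30, 2, 5)
        assert chi2 == 0.0
        assert p == 1.0

    def test_arithmetic_of_stated_formula(self):
        chi2, df, p = bartlett_chi2_p(np.exp(-1.0), n=101, G=2, m=4)
        assert chi2 == pytest.approx(97.0)
        assert df == 4

    def test_small_sample_scale_factor_rejected(self):
        with pytest.raises(ValueError, match="small"):
            bartlett_chi2_p(0.5, n=4, G=2, m=8)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            bartlett_chi2_p(1.5, 30, 2, 3)

    def test_bartlett_p_approaches_pooled_t_p_univariate(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = np.r_[rng.standard_normal(n // 2) + 0.05, rng.standard_normal(n // 2)]
        groups = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        _, _, _, p_bartlett = wilks_test(x, groups)
        _, _, p_t = pooled_t_test(x[: n // 2], x[n // 2:])
        assert abs(p_bartlett - p_t) < 0.005


class TestScreen:
    def test_single_roi_matches_low_level_composition(self, null_features):
        fs, labels = null_features
        out = screen_rois(fs, labels, {"dti": ["dti"]})
        row = out[out["roi"] == 3].iloc[0]
        cols = fs.block_columns("dti")
        lam, chi2, df, p = wilks_test(fs.data[:, 3, cols], labels)
        assert row["lam"] == pytest.approx(lam, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-12)
        assert row["df"] == df

    def test_infeasible_roi_flagged_not_dropped(self, null_features):
        fs, labels = null_features
        # fusion m = 5+2+3 = 10 but keep only 11 subjects: n <= m+G
        small = FusionFeatureSet(
            data=fs.data[:11], blocks=fs.blocks, feature_names=fs.feature_names
        )
        out = screen_rois(small, labels[:11], {"fusion": ["fmri", "smri", "dti"]})
        assert out["p"].isna().all()
        assert (out["reason"] != "").all()

    def test_injected_gm_effect_ranks_first_for_smri_and_fusion(self, effect_cohort):
        from roifuse import cohort_features, zscore_normalize

        cohort, truth = effect_cohort
        fs = zscore_normalize(cohort_features(cohort))
        out = screen_rois(fs, cohort.labels, {"smri": ["smri"], "dti": ["dti"]})
        best_smri = out[out["measure"] == "smri"].nsmallest(1, "p")["roi"].item()
        assert best_smri in truth.affected_rois

    def test_tally_counts_sum_to_roi_count(self, null_features):
        fs, labels = null_features
        out = screen_rois(fs, labels)
        tally = tally_best_measure(out)
        assert tally.sum() == fs.n_roi

    def test_tally_degenerate_dominance(self):
        df = pd.DataFrame(
            [
                {"roi": r, "measure": m, "p": 0.001 if m == "dti" else 0.5}
                for r in range(4)
                for m in ("fmri", "dti")
            ]
        )
        tally = tally_best_measure(df)
        assert tally["dti"] == 4 and tally["fmri"] == 0

    def test_tally_tie_broken_by_precedence_with_warning(self):
        df = pd.DataFrame(
            [
                {"roi": 0, "measure": "smri", "p": 0.01},
                {"roi": 0, "measure": "fusion", "p": 0.01},
            ]
        )
        with pytest.warns(UserWarning, match="tie"):
            tally = tally_best_measure(df)
        assert tally["fusion"] == 1 and tally["smri"] == 0


class TestMatchingTests:
    def test_age_summary_statistics_reproduce_reported_t(self):
        t, df, p = pooled_t_test((44.99, 11.5, 161), (43.17, 10.8, 168))
        assert round(t, 2) == 1.48
        assert round(p, 2) == 0.14

    def test_education_summary_statistics_reproduce_reported_t(self):
        t, _, p = pooled_t_test((12.33, 3.66, 161), (15.8, 3.5, 168))
        assert round(t, 1) == -8.8
        assert p < 0.001

    def test_identical_summaries_give_t_zero_p_one(self):
        t, _, p = pooled_t_test((1.0, 2.0, 10), (1.0, 2.0, 12))
        assert t == 0.0 and p == 1.0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pooled_t_test((1.0, 0.0, 5), (2.0, 0.0, 5))

    def test_sex_table_reproduces_reported_p(self):
        chi2, df, p = pearson_chi2_2x2(66, 95, 72, 96)
        assert df == 1
        assert round(p, 2) == 0.73

    def test_identical_row_proportions_give_zero(self):
        chi2, _, p = pearson_chi2_2x2(10, 20, 5, 10)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_computed(self):
        chi2, _, p = pearson_chi2_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)
        assert p < 1e-4

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2_2x2(0, 0, 3, 4)
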