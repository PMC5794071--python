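"""Fusion feature construction: FC vectors, diffusion scalars, assembly,
normalisation, PCA reduction and the covariate confound screen."""

import numpy as np
import pytest
from scipy import stats

from roifuse import (
    ModalityFeatures,
    SynthCohortConfig,
    assemble_fusion,
    cohort_features,
    confound_cca_screen,
    dti_scalars,
    fc_vector,
    fisher_z,
    generate_cohort,
    pca_reduce_fmri_block,
    zscore_normalize,
)
from roifuse.features import dti_features, fc_features, smri_features


@pytest.fixture(scope="module")
def cohort90():
    """Twelve subjects on the full 90-ROI atlas (enough rank for 5-PC reduction)."""
    cfg = SynthCohortConfig(n_per_group=6, n_roi=90, n_timepoints=120, seed=5)
    cohort, _ = generate_cohort(cfg)
    return cohort


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert np.isclose(fisher_z(0.5), 0.5 * np.log(3))

    def test_strictly_increasing(self):
        r = np.linspace(-0.99, 0.99, 101)
        assert np.all(np.diff(fisher_z(r)) > 0)

    def test_perfect_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestFCVector:
    def test_length_is_n_roi_minus_one(self, cohort90):
        vec = fc_vector(cohort90.timeseries[0], roi=0)
        assert vec.shape == (89,)

    def test_orthogonal_series_give_zero(self):
        ts = np.vstack([np.tile([1.0, -1.0], 10), np.tile([1.0, 1.0, -1.0, -1.0], 5)])
        assert fc_vector(ts, 0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_across_rois(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((5, 60))
        # entry of ROI 1 in ROI 3's vector equals entry of ROI 3 in ROI 1's
        assert fc_vector(ts, 3)[1] == pytest.approx(fc_vector(ts, 1)[2], rel=1e-12)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        ts = rng.standard_normal((4, 50))
        scaled = ts.copy()
        scaled[2] = 5.0 * scaled[2] - 3.0
        assert np.allclose(fc_vector(ts, 0), fc_vector(scaled, 0))

    def test_zero_variance_roi_named_in_error(self):
        ts = np.random.default_rng(2).standard_normal((4, 30))
        ts[2] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            fc_vector(ts, 0)


class TestDTIScalars:
    def test_isotropic_tensor(self):
        fa, rd, md = dti_scalars([2.0, 2.0, 2.0])
        assert fa == pytest.approx(0.0)
        assert rd == pytest.approx(2.0)
        assert md == pytest.approx(2.0)

    def test_fully_anisotropic_limit(self):
        fa, rd, md = dti_scalars([1.0, 0.0, 0.0])
        assert fa == pytest.approx(1.0)
        assert rd == pytest.approx(0.0)
        assert md == pytest.approx(1.0 / 3.0)

    def test_matches_direct_formula_evaluation(self):
        ev = np.array([1.5e-3, 1.0e-3, 0.5e-3])
        fa, rd, md = dti_scalars(ev)
        assert md == pytest.approx(1.0e-3)
        assert rd == pytest.approx(0.75e-3)
        lbar = ev.mean()
        fa_direct = np.sqrt(1.5 * np.sum((ev - lbar) ** 2) / np.sum(ev**2))
        assert fa == pytest.approx(fa_direct, rel=1e-12)
        assert 0.0 <= fa <= 1.0

    def test_all_zero_eigenvalues_warn_fa_zero(self):
        with pytest.warns(UserWarning, match="FA set to 0"):
            fa, _, _ = dti_scalars([0.0, 0.0, 0.0])
        assert fa == 0.0

    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            dti_scalars([0.5, 1.0, 1.5])


class TestAssembly:
    def test_full_fusion_width_94(self, cohort90):
        fs = cohort_features(cohort90)
        assert fs.width == 94
        assert (fs.blocks == "fmri").sum() == 89
        assert (fs.blocks == "smri").sum() == 2
        assert (fs.blocks == "dti").sum() == 3

    def test_smri_dti_only_width_5(self, cohort90):
        fs = cohort_features(cohort90, blocks=["smri", "dti"])
        assert fs.width == 5

    def test_pca_reduced_fusion_width_10(self, cohort90):
        fs = cohort_features(cohort90)
        reduced, explained = pca_reduce_fmri_block(fs, k=5)
        assert reduced.width == 10
        assert np.all((explained > 0) & (explained <= 1))

    def test_subject_count_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        smri = smri_features(rng.standard_normal((4, 3)), rng.standard_normal((4, 3)))
        dti = dti_features(*(rng.standard_normal((5, 3)) for _ in range(3)))
        with pytest.raises(ValueError, match="disagree"):
            assemble_fusion(smri, dti)

    def test_block_order_is_fmri_smri_dti(self, cohort90):
        fs = cohort_features(cohort90)
        labels = fs.blocks.tolist()
        assert labels == ["fmri"] * 89 + ["smri"] * 2 + ["dti"] * 3

    def test_restrict_preserves_subjects_and_tags(self, cohort90):
        fs = cohort_features(cohort90)
        sub = fs.restrict(["dti"])
        assert sub.width == 3
        assert sub.subject_ids == fs.subject_ids
        assert np.array_equal(sub.data, fs.data[:, :, 91:])


class TestNormalisation:
    def test_global_fit_centres_every_column(self, cohort90):
        fs = zscore_normalize(cohort_features(cohort90))
        assert np.allclose(fs.data.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(fs.data.std(axis=0), 1.0, atol=1e-8)
        assert fs.normalized

    def test_train_fit_leaves_test_uncentred(self, cohort90):
        fs = cohort_features(cohort90)
        train = np.arange(0, 8)
        test = np.arange(8, 12)
        out = zscore_normalize(fs, fit_on=train)
        assert np.allclose(out.data[train].mean(axis=0), 0.0, atol=1e-8)
        assert not np.allclose(out.data[test].mean(axis=0), 0.0, atol=1e-3)

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(4)
        gm = rng.standard_normal((6, 2))
        wm = np.ones((6, 2))
        fs = assemble_fusion(smri_features(gm, wm))
        with pytest.raises(ValueError, match="zero-SD"):
            zscore_normalize(fs)


class TestPCAReduction:
    def test_rank_two_data_fully_explained_by_two_components(self):
        rng = np.random.default_rng(5)
        basis = rng.standard_normal((2, 8))
        data = (rng.standard_normal((20, 2)) @ basis)[:, None, :]
        fmri = ModalityFeatures("fmri", np.repeat(data, 9, axis=1)[:, :, :8], [["f"] * 8] * 9)
        fs = assemble_fusion(fmri)
        reduced, explained = pca_reduce_fmri_block(fs, k=2)
        assert np.allclose(explained, 1.0)

    def test_full_width_fully_explained(self, cohort90):
        fs = cohort_features(cohort90, blocks=["fmri"])
        # rank is capped by n_subjects-1 = 11 < 89
        _, explained = pca_reduce_fmri_block(fs, k=11)
        assert np.allclose(explained, 1.0, atol=1e-8)

    def test_explained_fraction_monotone_in_k(self, cohort90):
        fs = cohort_features(cohort90)
        fractions = [pca_reduce_fmri_block(fs, k=k)[1].mean() for k in (1, 3, 5)]
        assert np.all(np.diff(fractions) > 0)

    def test_scores_match_eigendecomposition_oracle(self, cohort90):
        fs = cohort_features(cohort90, blocks=["fmri"])
        reduced, _ = pca_reduce_fmri_block(fs, k=5)
        roi = 7
        block = fs.data[:, roi, :]
        centred = block - block.mean(axis=0)
        evals, evecs = np.linalg.eigh(centred.T @ centred)
        order = np.argsort(evals)[::-1][:5]
        oracle = centred @ evecs[:, order]
        for j in range(5):  # agreement up to per-component sign
            got = reduced.data[:, roi, j]
            assert np.allclose(got, oracle[:, j], atol=1e-8) or np.allclose(
                got, -oracle[:, j], atol=1e-8
            )

    def test_k_beyond_rank_rejected(self, cohort90):
        fs = cohort_features(cohort90, blocks=["fmri"])
        with pytest.raises(ValueError, match="rank"):
            pca_reduce_fmri_block(fs, k=50)  # > n_subjects-1 = 11


class TestConfoundScreen:
    def test_covariate_equal_to_feature_gives_unit_correlation(self, null_features):
        fs, _ = null_features
        cov = fs.data[:, 0, 3].copy()
        out = confound_cca_screen(fs, cov)
        assert out.loc[out["roi"] == 0, "canonical_correlation"].item() == pytest.approx(1.0, abs=1e-6)

    def test_single_feature_reduces_to_pearson(self, null_cohort):
        cohort, _ = null_cohort
        fs = zscore_normalize(cohort_features(cohort, blocks=["smri"])).restrict(["smri"])
        one = fs.restrict(["smri"])
        one.data = one.data[:, :, :1]
        one.blocks = one.blocks[:1]
        rng = np.random.default_rng(6)
        cov = rng.standard_normal(fs.n_subjects)
        out = confound_cca_screen(one, cov)
        r = abs(stats.pearsonr(one.data[:, 2, 0], cov)[0])
        assert out.loc[out["roi"] == 2, "canonical_correlation"].item() == pytest.approx(r, abs=1e-10)

    def test_constant_covariate_rejected(self, null_features):
        fs, _ = null_features
        with pytest.raises(ValueError, match="constant"):
            confound_cca_screen(fs, np.ones(fs.n_subjects))

    def test_null_covariate_rarely_flagged_under_fdr(self):
        # complete null: P(any BH discovery) <= alpha per replicate
        hits = 0
        for seed in range(40):
            cfg = SynthCohortConfig(n_per_group=30, n_roi=5, n_timepoints=40, seed=seed)
            cohort, _ = generate_cohort(cfg)
            fs = zscore_normalize(cohort_features(cohort, blocks=["smri", "dti"]))
            cov = np.random.default_rng(1000 + seed).standard_normal(fs.n_subjects)
            out = confound_cca_screen(fs, cov, alpha=0.05)
            hits += int(out["significant"].any())
        assert hits <= 7  # Binomial(40, 0.05): P(>7) < 1e-3
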