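"""Preprocessing: trial averaging, HC standardization, flattening, PCA, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitsubpop as g
from gaitsubpop.preprocess import unflatten


class TestAverageTrials:
    def test_identical_trials_idempotent(self, small_study):
        study = g.WaveformStudy(
            subjects=small_study.subjects,
            data=np.repeat(small_study.data[:, :1], 3, axis=1),
            channel_names=small_study.channel_names,
        )
        np.testing.assert_allclose(g.average_trials(study), study.data[:, 0], rtol=1e-14)

    def test_matches_brute_force_mean(self, small_study):
        # brute-force elementwise loop oracle on one subject
        out = g.average_trials(small_study)
        s = 3
        expected = np.zeros_like(out[s])
        for tr in range(small_study.data.shape[1]):
            expected += small_study.data[s, tr]
        expected /= small_study.data.shape[1]
        np.testing.assert_allclose(out[s], expected, rtol=0, atol=1e-12)

    def test_simple_values(self, small_study):
        study = g.WaveformStudy(
            subjects=small_study.subjects.iloc[:1].assign(group="HC", paired_id=None),
            data=np.arange(3, dtype=float).reshape(1, 3, 1, 1)
            * np.ones((1, 3, 18, 101)),
            channel_names=small_study.channel_names,
        )
        assert g.average_trials(study)[0, 0, 0] == 1.0

    def test_missing_trials_named_in_error(self, small_study):
        data = small_study.data.copy()
        data[2, 1] = np.nan
        study = g.WaveformStudy.__new__(g.WaveformStudy)
        study.subjects = small_study.subjects
        study.data = data
        study.channel_names = small_study.channel_names
        with pytest.raises(ValueError, match=small_study.subjects.subject_id.iat[2]):
            g.average_trials(study)


class TestStandardization:
    def test_two_point_formula(self):
        hc = np.zeros((2, 1, 1))
        hc[1] = 2.0
        stats = g.fit_standardization(hc)
        assert stats.mean[0, 0] == 1.0
        assert stats.sd[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_constant_channel_is_an_error(self, rng):
        hc = rng.normal(size=(5, 2, 3))
        hc[:, 1, 2] = 7.0
        with pytest.raises(ValueError, match="channel index 1, timepoint 2"):
            g.fit_standardization(hc)

    def test_matches_loop_oracle(self, rng):
        hc = rng.normal(size=(50, 3, 7))
        stats = g.fit_standardization(hc)
        for c in range(3):
            for t in range(7):
                col = hc[:, c, t]
                assert stats.mean[c, t] == pytest.approx(col.mean(), abs=1e-12)
                assert stats.sd[c, t] == pytest.approx(col.std(ddof=1), abs=1e-12)

    def test_self_standardization_gives_mean0_sd1(self, rng):
        hc = rng.normal(2.0, 3.0, size=(20, 4, 9))
        stats = g.fit_standardization(hc)
        z = g.standardize(hc, stats)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_mean_input_gives_zeros(self, rng):
        hc = rng.normal(size=(10, 2, 5))
        stats = g.fit_standardization(hc)
        z = g.standardize(stats.mean[None], stats)
        assert np.abs(z).max() == 0

    def test_shape_mismatch_rejected(self, rng):
        hc = rng.normal(size=(10, 2, 5))
        stats = g.fit_standardization(hc)
        with pytest.raises(ValueError, match="mismatch"):
            g.standardize(rng.normal(size=(3, 2, 6)), stats)

    def test_planted_offset_recovers_in_standard_units(self):
        # a +2 HC-SD constant offset on one channel must standardize to ~ +2
        eff = g.SubpopEffect(
            subpop_id=1,
            effect_curves={"hip_flexion_angle": lambda t: np.ones_like(t)},
            magnitude=2.0,
        )
        cfg = g.CohortConfig(n_per_subpop=(60,), n_hc=60, n_followup_per_subpop=(0,),
                             recovery_fraction=(0.0,), seed=3)
        study = g.generate_cohort(cfg, effects=[eff])
        means = g.average_trials(study)
        stats = g.fit_standardization(means[study.group_index("HC")])
        z = g.standardize(means[study.group_index("HOA")], stats)
        ci = study.channel_names.index("hip_flexion_angle")
        assert z[:, ci, :].mean() == pytest.approx(2.0, abs=0.35)


class TestFlatten:
    def test_canonical_grid_is_1818(self, small_study):
        means = g.average_trials(small_study)
        assert g.flatten(means).shape[1] == 18 * 101 == 1818

    def test_indexing_law(self, rng):
        x = rng.normal(size=(4, 18, 101))
        flat = g.flatten(x)
        assert flat[2, 5 * 101 + 17] == x[2, 5, 17]

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(1, 4), c=st.integers(1, 5), t=st.integers(2, 8),
        seed=st.integers(0, 1000),
    )
    def test_round_trip(self, n, c, t, seed):
        x = np.random.default_rng(seed).normal(size=(n, c, t))
        assert np.array_equal(unflatten(g.flatten(x), c, t), x)


class TestPCA:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=6)
        x = np.outer(rng.normal(size=10), direction) + 3.0
        basis = g.fit_pca(x, 0.90)
        assert basis.n_retained == 1
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_bound(self, rng):
        x = rng.normal(size=(200, 5))
        basis = g.fit_pca(x, 0.90)
        assert basis.n_retained <= 5
        assert basis.explained_variance_ratio.sum() >= 0.90

    def test_matches_covariance_eigendecomposition(self, rng):
        # brute-force oracle: eigendecompose the sample covariance directly
        x = rng.normal(size=(20, 8))
        basis = g.fit_pca(x, 1.0)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (len(x) - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(
            basis.explained_variance_ratio, evals[: basis.n_retained] / evals.sum(),
            rtol=1e-9,
        )
        for j in range(basis.n_retained):
            v = evecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:  # apply the same sign convention
                v = -v
            np.testing.assert_allclose(basis.eigenvectors[:, j], v, atol=1e-8)

    def test_orthonormal_columns(self, small_reduced):
        _, basis, _ = small_reduced
        gram = basis.eigenvectors.T @ basis.eigenvectors
        assert np.abs(gram - np.eye(basis.n_retained)).max() < 1e-8

    def test_threshold_monotone_in_retained_components(self, rng):
        x = rng.normal(size=(40, 12)) @ np.diag(np.linspace(3, 0.2, 12))
        retained = [g.fit_pca(x, thr).n_retained for thr in (0.5, 0.7, 0.9, 0.99, 1.0)]
        assert retained == sorted(retained)

    def test_minimality_of_retained_count(self, rng):
        x = rng.normal(size=(40, 12)) @ np.diag(np.linspace(3, 0.2, 12))
        basis = g.fit_pca(x, 0.9)
        cum = np.cumsum(basis.explained_variance_ratio)
        assert cum[-1] >= 0.9
        if basis.n_retained > 1:
            assert cum[-2] < 0.9

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError, match="threshold"):
            g.fit_pca(rng.normal(size=(5, 3)), 1.5)


class TestProjection:
    def test_fitting_cohort_self_consistency(self, rng):
        x = rng.normal(size=(15, 6))
        basis = g.fit_pca(x, 1.0)
        scores = g.project(x, basis).scores
        xc = x - basis.center
        np.testing.assert_allclose(scores, xc @ basis.eigenvectors, atol=1e-10)

    def test_center_row_maps_to_origin(self, rng):
        x = rng.normal(size=(15, 6))
        basis = g.fit_pca(x, 0.9)
        scores = g.project(basis.center[None], basis).scores
        assert np.abs(scores).max() < 1e-10

    def test_reconstruction_explains_threshold_variance(self, rng):
        # variance bookkeeping oracle
        x = rng.normal(size=(30, 10)) @ np.diag(np.linspace(2, 0.3, 10))
        basis = g.fit_pca(x, 0.9)
        scores = g.project(x, basis).scores
        recon = basis.center + scores @ basis.eigenvectors.T
        total = ((x - x.mean(axis=0)) ** 2).sum()
        explained = ((recon - x.mean(axis=0)) ** 2).sum()
        assert explained / total >= 0.9

    def test_dimension_mismatch_rejected(self, rng):
        basis = g.fit_pca(rng.normal(size=(15, 6)), 0.9)
        with pytest.raises(ValueError, match="columns"):
            g.project(rng.normal(size=(3, 5)), basis)


def test_eigenbasis_save_load_round_trip(small_reduced, tmp_path):
    _, basis, _ = small_reduced
    basis.save(tmp_path / "basis")
    back = g.EigenBasis.load(tmp_path / "basis")
    np.testing.assert_array_equal(back.eigenvectors, basis.eigenvectors)
    np.testing.assert_array_equal(back.center, basis.center)
    assert back.variance_threshold == basis.variance_threshold
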