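import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sonoforce.features import (
    DegenerateWindowWarning,
    FeatureMatrix,
    apply_feature_transform,
    concat_sites,
    extract_features,
    extract_frame_features,
    fit_feature_transform,
    mean_depth,
    window_starts,
)
from sonoforce.mmode import MModeImage, pixel_centers
from sonoforce.phantom import render_mmode


def brute_force_mean_depth(A, D):
    """Independent loop oracle for the weighted mean-depth formula."""
    num = 0.0
    den = 0.0
    for a, d in zip(A, D):
        num += a * d
        den += a
    return num / den


class TestMeanDepth:
    def test_uniform_weights_midpoint(self):
        assert mean_depth([1, 1, 1, 1], [10, 11, 12, 13]) == pytest.approx(11.5)

    def test_point_mass(self):
        assert mean_depth([0, 0, 4, 0], [1, 2, 3, 4]) == pytest.approx(3.0)

    def test_hand_value(self):
        # (1*5 + 2*6 + 3*7) / (1+2+3) = 38/6
        assert mean_depth([1, 2, 3], [5, 6, 7]) == pytest.approx(38 / 6)

    def test_zero_sum_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            mean_depth([0, 0, 0], [1, 2, 3])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            mean_depth([1, -1, 1], [1, 2, 3])

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(1, 40),
        data=st.data(),
    )
    def test_oracle_equivalence(self, n, data):
        A = data.draw(arrays(float, n, elements=st.floats(0, 100)))
        if A.sum() == 0:
            A[0] = 1.0
        D = data.draw(arrays(float, n, elements=st.floats(-50, 50)))
        assert mean_depth(A, D) == pytest.approx(brute_force_mean_depth(A, D),
                                                 rel=1e-12, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(2, 20),
        delta=st.floats(-10, 10),
        scale=st.floats(0.01, 100),
        data=st.data(),
    )
    def test_translation_and_scale_invariance(self, n, delta, scale, data):
        A = data.draw(arrays(float, n, elements=st.floats(0.01, 100)))
        D = data.draw(arrays(float, n, elements=st.floats(0, 10)))
        base = mean_depth(A, D)
        # shifting depths shifts the result by exactly the shift
        assert mean_depth(A, D + delta) == pytest.approx(base + delta, abs=1e-9)
        # scaling intensities leaves the result unchanged
        assert mean_depth(A * scale, D) == pytest.approx(base, rel=1e-12)

    def test_within_depth_range(self, rng):
        A = rng.random(25)
        D = np.sort(rng.random(25) * 4)
        md = mean_depth(A, D)
        assert D.min() <= md <= D.max()


class TestWindowing:
    def test_default_stride_is_12(self):
        _, stride = window_starts(256, 25, 0.5)
        assert stride == 12

    def test_window_count_256(self):
        starts, _ = window_starts(256, 25, 0.5)
        assert len(starts) == 20  # floor((256 - 25) / 12) + 1

    def test_window_count_128(self):
        starts, _ = window_starts(128, 25, 0.5)
        assert len(starts) == 9

    def test_too_short_aline(self):
        with pytest.raises(ValueError, match="shorter"):
            extract_frame_features(np.ones(10), np.arange(10.0), window_px=25)

    def test_uniform_aline_gives_window_centers(self):
        axis = pixel_centers(256, 4.0)
        feats = extract_frame_features(np.ones(256), axis)
        starts, _ = window_starts(256, 25, 0.5)
        expected = np.array([axis[s:s + 25].mean() for s in starts])
        np.testing.assert_allclose(feats, expected)

    def test_single_bright_pixel(self):
        axis = pixel_centers(256, 4.0)
        aline = np.zeros(256)
        aline[10] = 7.0
        with pytest.warns(DegenerateWindowWarning):
            feats = extract_frame_features(aline, axis)
        assert feats[0] == pytest.approx(axis[10])

    def test_degenerate_window_fallback_is_central_depth(self):
        axis = pixel_centers(256, 4.0)
        with pytest.warns(DegenerateWindowWarning):
            feats = extract_frame_features(np.zeros(256), axis)
        starts, _ = window_starts(256, 25, 0.5)
        expected = np.array([axis[s:s + 25].mean() for s in starts])
        np.testing.assert_allclose(feats, expected)


class TestExtractFeatures:
    def test_row_count_matches_frames(self, dataset):
        img = dataset.trials[0].images["vl"]
        fm = extract_features(img)
        assert fm.n_frames == 250
        assert fm.n_features == 9
        assert fm.feature_labels[0] == ("vl", 0)

    def test_static_image_identical_rows(self):
        img = render_mmode(np.full((1, 20), 2.0), 50.0, 128)
        fm = extract_features(img)
        np.testing.assert_allclose(fm.values, fm.values[:1, :].repeat(20, axis=0))

    def test_rows_equal_frame_features(self, rng):
        img = MModeImage(rng.random((128, 7)) + 0.01, pixel_centers(128, 4.0), 50.0)
        fm = extract_features(img)
        for t in range(7):
            np.testing.assert_allclose(
                fm.values[t], extract_frame_features(img.intensities[:, t],
                                                     img.depth_axis))

    def test_moving_interface_monotone_within_window(self):
        # interface sweeping within one window's depth span -> that window's
        # feature tracks it monotonically
        traj = np.linspace(1.65, 1.85, 40)[None, :]
        img = render_mmode(traj, 50.0, 128)
        fm = extract_features(img)
        # window 4 spans pixels 48..72 ~ 1.5-2.28 cm
        assert np.all(np.diff(fm.values[:, 4]) > 0)


class TestFeatureTransform:
    def test_rank2_data_retains_two_components(self, rng):
        # rank-2 generative model + tiny noise -> 2 components at 99%
        n = 400
        latent = rng.normal(size=(n, 2))
        loadings = rng.normal(size=(2, 10))
        X = latent @ loadings + 1e-6 * rng.normal(size=(n, 10))
        tr = fit_feature_transform(X, variance_threshold=0.99)
        assert tr.n_components == 2

    def test_threshold_one_keeps_all_nonzero(self, rng):
        X = rng.normal(size=(50, 5))
        tr = fit_feature_transform(X, variance_threshold=1.0)
        assert tr.n_components == 5

    def test_training_zscores_standardized(self, rng):
        X = rng.normal(loc=3.0, scale=2.0, size=(200, 6))
        tr = fit_feature_transform(X)
        Z = (X - tr.z_means) / tr.z_sds
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_orthonormal_loadings(self, rng):
        X = rng.normal(size=(100, 8))
        tr = fit_feature_transform(X, variance_threshold=1.0)
        gram = tr.pca_components @ tr.pca_components.T
        np.testing.assert_allclose(gram, np.eye(tr.n_components), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(60, 5))
        tr = fit_feature_transform(X, variance_threshold=1.0)
        for row in tr.pca_components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_zero_variance_feature_guarded(self, rng):
        X = rng.normal(size=(50, 4))
        X[:, 2] = 7.0  # constant column
        tr = fit_feature_transform(X)
        assert tr.z_sds[2] == 1.0
        Z = (X - tr.z_means) / tr.z_sds
        np.testing.assert_allclose(Z[:, 2], 0.0)

    def test_apply_consistent_with_fit(self, rng):
        X = rng.normal(size=(100, 6))
        tr = fit_feature_transform(X)
        scores1 = apply_feature_transform(tr, X).values
        scores2 = apply_feature_transform(tr, X).values
        np.testing.assert_allclose(scores1, scores2, atol=1e-10)

    def test_projection_does_not_inflate_variance(self, rng):
        X = rng.normal(size=(120, 7))
        tr = fit_feature_transform(X, variance_threshold=0.9)
        Z = (X - tr.z_means) / tr.z_sds
        scores = apply_feature_transform(tr, X).values
        assert scores.var(axis=0).sum() <= Z.var(axis=0).sum() + 1e-10

    def test_dimension_mismatch(self, rng):
        tr = fit_feature_transform(rng.normal(size=(30, 4)))
        with pytest.raises(ValueError, match="features"):
            apply_feature_transform(tr, rng.normal(size=(10, 5)))

    def test_no_leakage_from_held_out_rows(self, rng):
        # transform statistics depend only on training rows
        X_train = rng.normal(size=(80, 5))
        tr1 = fit_feature_transform(X_train)
        tr2 = fit_feature_transform(X_train.copy())
        np.testing.assert_array_equal(tr1.z_means, tr2.z_means)
        np.testing.assert_array_equal(tr1.pca_components, tr2.pca_components)

    def test_json_round_trip(self, rng, tmp_path):
        from sonoforce.features import FeatureTransform
        tr = fit_feature_transform(rng.normal(size=(40, 5)))
        tr.to_json(tmp_path / "tr.json")
        back = FeatureTransform.from_json(tmp_path / "tr.json")
        np.testing.assert_allclose(back.pca_components, tr.pca_components)
        np.testing.assert_allclose(back.z_means, tr.z_means)


class TestConcatSites:
    def _fm(self, rng, site, frames=250, feats=20):
        values = rng.random((frames, feats))
        labels = [(site, w) for w in range(feats)]
        return FeatureMatrix(values, labels, 50.0)

    def test_four_sites_concatenated(self, rng):
        mats = [self._fm(rng, s) for s in ("vl", "rf", "mh", "vmo")]
        out = concat_sites(mats)
        assert out.values.shape == (250, 80)

    def test_single_input_identity(self, rng):
        m = self._fm(rng, "vl")
        out = concat_sites([m])
        np.testing.assert_array_equal(out.values, m.values)

    def test_indexing_oracle(self, rng):
        mats = [self._fm(rng, s) for s in ("vl", "rf", "mh", "vmo")]
        out = concat_sites(mats)
        probes = rng.integers(0, 20, size=10)
        for si, m in enumerate(mats):
            for w in probes:
                col = si * 20 + w
                assert out.feature_labels[col] == m.feature_labels[w]
                np.testing.assert_array_equal(out.values[:, col], m.values[:, w])

    def test_frame_mismatch_reports_counts(self, rng):
        mats = [self._fm(rng, "vl", frames=250), self._fm(rng, "rf", frames=200)]
        with pytest.raises(ValueError, match="vl=250.*rf=200"):
            concat_sites(mats)
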