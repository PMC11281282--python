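import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shgfiber import FcmConfig, ShgImage, fuzzy_c_means, preprocess, segment_fibers
from shgfiber.segmentation import DegenerateInputError

from _oracles import fcm_oracle_best


class TestPreprocess:
    def test_identity_settings_leave_image_unchanged(self):
        img = ShgImage(np.random.default_rng(0).random((16, 16)) * 50)
        out = preprocess(img, median_radius_px=0, background_percentile=0)
        np.testing.assert_array_equal(out.intensities, img.intensities)

    def test_high_percentile_zeroes_constant_image(self):
        img = ShgImage(np.full((10, 10), 7.0))
        out = preprocess(img, median_radius_px=0, background_percentile=99.9)
        np.testing.assert_array_equal(out.intensities, 0.0)

    def test_median_filter_removes_hot_pixel(self):
        data = np.full((11, 11), 3.0)
        data[5, 5] = 1000.0
        out = preprocess(ShgImage(data), median_radius_px=1, background_percentile=0)
        np.testing.assert_array_equal(out.intensities, 3.0)

    def test_invalid_settings_raise(self):
        img = ShgImage(np.ones((4, 4)))
        with pytest.raises(ValueError):
            preprocess(img, median_radius_px=-1)
        with pytest.raises(ValueError):
            preprocess(img, background_percentile=100.0)


class TestFuzzyCMeans:
    def test_two_point_masses_recover_exact_centroids(self):
        res = fuzzy_c_means([0, 0, 0, 10, 10, 10], FcmConfig())
        np.testing.assert_allclose(res.centroids, [0.0, 10.0], atol=1e-8)
        # zero-distance rule: value-0 pixels belong fully to cluster 0
        np.testing.assert_allclose(res.membership[:3, 0], 1.0)
        np.testing.assert_allclose(res.membership[3:, 1], 1.0)

    def test_memberships_are_a_partition(self):
        rng = np.random.default_rng(5)
        res = fuzzy_c_means(rng.random(300) * 100, FcmConfig(n_clusters=3))
        np.testing.assert_allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
        assert res.membership.min() >= 0
        assert res.membership.max() <= 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=5, max_size=60),
        st.floats(1.3, 4.0),
    )
    def test_objective_never_increases(self, values, m):
        if len(set(values)) < 2:
            return
        res = fuzzy_c_means(values, FcmConfig(fuzziness=m))
        assert np.all(np.diff(res.objective_history) <= 1e-9 * (1 + res.objective_history[0]))

    def test_matches_brute_force_restart_oracle_on_small_input(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(5, 1, 30), rng.normal(20, 2, 30)])
        best = fcm_oracle_best(x, c=2, m=2.0, restarts=10)
        ours = fuzzy_c_means(x, FcmConfig(tol=1e-9, max_iter=1000)).objective
        assert ours <= best + 1e-6

    def test_too_few_distinct_values_raise(self):
        with pytest.raises(DegenerateInputError):
            fuzzy_c_means([4.0, 4.0, 4.0], FcmConfig(n_clusters=2))

    def test_near_crisp_limit_matches_kmeans(self):
        """As m -> 1+, FCM hard assignments coincide with k-means."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 0.5, 80), rng.normal(30, 0.5, 80)])
        res = fuzzy_c_means(x, FcmConfig(fuzziness=1.05))
        hard = res.membership.argmax(axis=1)
        km = KMeans(n_clusters=2, n_init=1, init=res.centroids.reshape(-1, 1)).fit(
            x.reshape(-1, 1)
        )
        centers = km.cluster_centers_.ravel()
        relabel = np.argsort(np.argsort(centers))  # align to ascending order
        assert np.array_equal(hard, relabel[km.labels_])

    def test_random_init_is_seeded(self):
        x = np.random.default_rng(1).random(100) * 10
        a = fuzzy_c_means(x, FcmConfig(init="random", seed=11))
        b = fuzzy_c_means(x, FcmConfig(init="random", seed=11))
        np.testing.assert_array_equal(a.centroids, b.centroids)


class TestSegmentFibers:
    def test_two_plateaus_mask_the_bright_one(self):
        data = np.full((20, 20), 10.0)
        data[:, 10:] = 200.0
        mask = segment_fibers(ShgImage(data))
        expected = np.zeros((20, 20), dtype=bool)
        expected[:, 10:] = True
        np.testing.assert_array_equal(mask.mask, expected)

    def test_constant_image_yields_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = segment_fibers(ShgImage(np.full((8, 8), 3.0)))
        assert not mask.mask.any()
        assert mask.shape == (8, 8)

    def test_affine_intensity_rescaling_preserves_mask(self, high_snr_image):
        img, _ = high_snr_image
        small = ShgImage(img.intensities[:128, :128], pixel_size_um=img.pixel_size_um)
        scaled = ShgImage(3.5 * small.intensities + 40.0)
        np.testing.assert_array_equal(
            segment_fibers(small).mask, segment_fibers(scaled).mask
        )

    def test_stack_is_projected_by_default_and_per_slice_on_request(self):
        plane = np.full((10, 10), 5.0)
        bright = plane.copy()
        bright[4:6, :] = 150.0
        stack = ShgImage(np.stack([plane, bright]))
        proj_mask = segment_fibers(stack)
        assert proj_mask.shape == (10, 10)
        slice_mask = segment_fibers(stack, per_slice=True)
        assert slice_mask.shape == (2, 10, 10)
        np.testing.assert_array_equal(slice_mask.mask[1], proj_mask.mask)

    def test_recovers_synthetic_fibers(self, high_snr_image):
        """FCM alone (before shape filtering) overlaps the planted truth."""
        img, truth = high_snr_image
        mask = segment_fibers(preprocess(img))
        inter = np.logical_and(mask.mask, truth.mask).sum()
        union = np.logical_or(mask.mask, truth.mask).sum()
        assert inter / union >= 0.6
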