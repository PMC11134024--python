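"""Fuzzy C-means, alpha-cut filtering, and augmentation."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazetune import fda
from gazetune.fda import FuzzyPartition, ImageAugmentConfig
from gazetune.synthetic import SyntheticEyeImage, generate_eye_images


class TestFCM:
    def test_membership_columns_sum_to_one(self, blob_data):
        X, _, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        assert np.abs(part.U.sum(axis=0) - 1.0).max() <= 1e-9

    def test_recovers_separated_blob_means(self, blob_data):
        X, labels, true_centers = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        blob_means = np.array([X[labels == k].mean(axis=0) for k in range(3)])
        # match each fitted center to its nearest blob mean
        for c in part.centers:
            assert np.linalg.norm(blob_means - c, axis=1).min() < 0.1

    def test_identical_rows_collapse_centers(self):
        X = np.tile([2.0, -1.0, 3.0], (10, 1))
        part = fda.fcm_fit(X, c=2, seed=0)
        assert np.allclose(part.centers, X[0], atol=1e-8)

    def test_objective_non_increasing(self, blob_data):
        X, _, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        obj = np.array(part.objective)
        assert (np.diff(obj) <= 1e-8 * np.abs(obj[:-1]) + 1e-12).all()

    @pytest.mark.parametrize(
        "X,c,err",
        [
            (np.ones((2, 3)), 3, "at least"),
            (np.array([[np.nan, 1.0], [0.0, 1.0], [2.0, 1.0]]), 2, "finite"),
        ],
    )
    def test_invalid_inputs(self, X, c, err):
        with pytest.raises(ValueError, match=err):
            fda.fcm_fit(X, c=c, seed=0)

    def test_fuzzifier_must_exceed_one(self, blob_data):
        with pytest.raises(ValueError):
            fda.fcm_fit(blob_data[0], c=2, m=1.0, seed=0)


def _partition(U, X, centers=None):
    U = np.asarray(U, float)
    if centers is None:
        centers = np.zeros((U.shape[0], X.shape[1]))
    return FuzzyPartition(U=U, centers=np.asarray(centers, float),
                          X=np.asarray(X, float), m=2.0)


class TestMembershipMatrix:
    def test_rows_sorted_by_descending_grade(self):
        X = np.array([[2.0, 4.0]])
        part = _partition(np.array([[0.2], [0.7], [0.1]]), X)
        E = fda.build_membership_matrix(part, 0)
        assert np.allclose(E[0], 0.7 * X[0])
        assert np.allclose(E[1], 0.2 * X[0])
        assert np.allclose(E[2], 0.1 * X[0])

    def test_unit_membership_row_equals_record(self):
        X = np.array([[3.0, -1.0, 2.0]])
        part = _partition(np.array([[1.0], [0.0]]), X)
        E = fda.build_membership_matrix(part, 0)
        assert np.array_equal(E[0], X[0])

    def test_matches_bruteforce_sort_and_scale(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 3))
        U = rng.random((4, 5))
        U /= U.sum(axis=0)
        part = _partition(U, X)
        for i in range(5):
            expected = np.array(
                [mu * X[i] for mu in sorted(U[:, i], reverse=True)]
            )
            assert np.allclose(fda.build_membership_matrix(part, i), expected)

    def test_out_of_range_record_raises(self):
        part = _partition(np.array([[1.0], [0.0]]), np.ones((1, 2)))
        with pytest.raises(IndexError):
            fda.build_membership_matrix(part, 3)


class TestAlphaCut:
    def test_hand_example_retains_expected_rows(self):
        # records with max memberships 0.9, 0.3, 0.5 at alpha 0.4
        U = np.array([
            [0.90, 0.30, 0.50],
            [0.04, 0.30, 0.30],
            [0.03, 0.30, 0.10],
            [0.03, 0.10, 0.10],
        ])
        part = _partition(U, np.zeros((3, 2)))
        retained = fda.alpha_cut_filter(part, 0.4)
        assert set(int(i) for i in retained) == {0, 2}

    def test_alpha_zero_retains_everything(self, blob_data):
        X, _, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        assert len(fda.alpha_cut_filter(part, 0.0)) == len(X)

    def test_alpha_one_on_strictly_fuzzy_warns_empty(self):
        U = np.array([[0.6, 0.7], [0.4, 0.3]])
        part = _partition(U, np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="retains no records"):
            retained = fda.alpha_cut_filter(part, 1.0)
        assert len(retained) == 0

    def test_retention_monotone_in_alpha(self, blob_data):
        X, _, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        prev = None
        for alpha in np.linspace(0, 1, 21):
            cur = set(fda.alpha_cut_filter(part, alpha))
            if prev is not None:
                assert cur.issubset(prev)
            prev = cur

    @pytest.mark.parametrize("alpha", [-0.1, 1.5])
    def test_alpha_out_of_range_raises(self, blob_data, alpha):
        part = fda.fcm_fit(blob_data[0], c=3, seed=0)
        with pytest.raises(ValueError):
            fda.alpha_cut_filter(part, alpha)


class TestAugmentTable:
    def test_counts_and_ratio(self, blob_data):
        X, labels, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        aug = fda.augment_table(X, part, 0.25, labels)
        n_ret = len(fda.alpha_cut_filter(part, 0.25))
        assert len(aug.rows) == len(X) + n_ret
        assert aug.ratio == pytest.approx(n_ret / len(X))
        assert (aug.provenance == "augmented").sum() == n_ret

    def test_empty_retention_returns_input_unchanged(self, blob_data):
        X, labels, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        with pytest.warns(UserWarning):
            aug = fda.augment_table(X, part, 1.0, labels)
        assert np.array_equal(aug.rows, X)
        assert np.array_equal(aug.labels, labels)

    def test_original_rows_bit_identical(self, blob_data):
        X, labels, _ = blob_data
        digest = hashlib.sha256(X.tobytes()).hexdigest()
        part = fda.fcm_fit(X, c=3, seed=0)
        aug = fda.augment_table(X, part, 0.25, labels)
        n = len(X)
        assert hashlib.sha256(aug.rows[:n].tobytes()).hexdigest() == digest
        assert (aug.provenance[:n] == "original").all()

    def test_augmented_rows_labeled_by_cluster_majority(self, blob_data):
        X, labels, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        aug = fda.augment_table(X, part, 0.25, labels)
        hard = part.hard_labels()
        retained = fda.alpha_cut_filter(part, 0.25)
        n = len(X)
        for row_label, rec in zip(aug.labels[n:], retained):
            members = labels[hard == hard[rec]]
            vals, counts = np.unique(members, return_counts=True)
            assert row_label == vals[np.argmax(counts)]

    def test_label_length_mismatch_raises(self, blob_data):
        X, labels, _ = blob_data
        part = fda.fcm_fit(X, c=3, seed=0)
        with pytest.raises(ValueError):
            fda.augment_table(X, part, 0.25, labels[:-1])


class TestAugmentImage:
    def test_identity_transform_returns_input(self):
        [im] = generate_eye_images(1, size=32, seed=0, noise_sd=0.0)
        cfg = ImageAugmentConfig(rotation_range=(0.0, 0.0), noise="none")
        out = fda.augment_image(im, cfg, seed=1)
        assert np.array_equal(out.pixels, im.pixels)

    def test_saltpepper_flips_expected_pixel_count(self):
        img = SyntheticEyeImage(
            pixels=np.full((100, 100), 0.5),
            head_pose=np.zeros(3),
            gaze_target=(0.0, 0.0),
        )
        cfg = ImageAugmentConfig(
            rotation_range=(0.0, 0.0),
            saltpepper_density_range=(0.01, 0.01),
            noise="saltpepper",
        )
        out = fda.augment_image(img, cfg, seed=0)
        changed = int((out.pixels != img.pixels).sum())
        assert 70 <= changed <= 130  # Binomial(1e4, 0.01), 3 sigma
        assert set(np.unique(out.pixels[out.pixels != 0.5])) <= {0.0, 1.0}

    def test_output_clipped_to_unit_interval(self):
        [im] = generate_eye_images(1, size=32, seed=0)
        cfg = ImageAugmentConfig(gaussian_sd_range=(0.05, 0.05), noise="gaussian")
        out = fda.augment_image(im, cfg, seed=3)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert out.pixels.shape == im.pixels.shape

    def test_deterministic_for_seed(self):
        [im] = generate_eye_images(1, size=32, seed=0)
        a = fda.augment_image(im, seed=5)
        b = fda.augment_image(im, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_empty_image_raises(self):
        img = SyntheticEyeImage.__new__(SyntheticEyeImage)
        img.pixels = np.zeros((0, 0))
        img.head_pose = np.zeros(3)
        img.gaze_target = (0.0, 0.0)
        with pytest.raises(ValueError):
            fda.augment_image(img, seed=0)


class TestAlphaGridSearch:
    def test_picks_best_scoring_alpha_ties_to_larger(self):
        scores = {0.25: 0.8, 0.5: 0.9, 0.75: 0.9, 1.0: 0.7}
        best, got = fda.alpha_grid_search(list(scores), lambda a: scores[a])
        assert best == 0.75
        assert got == scores


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_memberships_normalized_for_random_data(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 3))
    part = fda.fcm_fit(X, c=3, seed=0, max_iter=50)
    assert np.abs(part.U.sum(axis=0) - 1.0).max() <= 1e-9
    assert part.U.min() >= 0.0 and part.U.max() <= 1.0
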