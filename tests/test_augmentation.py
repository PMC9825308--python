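"""Synthetic-sample operators: GCT, matrix mixup, colour-space rotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlmixup import (
    AugmentedSample,
    MixupCoefficientMatrix,
    MultiChannelImage,
    ThetaSampler,
    geometric_colour_transform,
    materialize_record,
    matrix_mixup,
    nonlinear_mixup,
    rotate_colour_space,
    rotation_matrix,
    sample_mixup_matrix,
)
from nlmixup.sampler import SupplementRecord


class TestGeometricColourTransform:
    def test_never_identity(self, random_image):
        sample = AugmentedSample(image=random_image(0), label_set={"3"})
        for seed in range(30):
            out = geometric_colour_transform(sample, seed)
            assert out.provenance["transforms"], "at least one transform applies"
            assert out.image.channels.shape == sample.image.channels.shape

    def test_label_set_unchanged(self, random_image):
        sample = AugmentedSample(image=random_image(1), label_set={"3", "9"})
        out = geometric_colour_transform(sample, 5)
        assert out.label_set == sample.label_set

    def test_values_stay_in_unit_interval(self, random_image):
        sample = AugmentedSample(image=random_image(2), label_set={"0"})
        for seed in range(20):
            out = geometric_colour_transform(sample, seed)
            assert out.image.channels.min() >= 0.0
            assert out.image.channels.max() <= 1.0

    def test_brightness_clips_at_one(self):
        arr = np.full((4, 4, 4), 0.9)
        scaled = np.clip(arr * 1.5, 0.0, 1.0)
        assert scaled.max() == 1.0  # 0.9 * 1.5 = 1.35 clips to 1.0

    def test_double_180_rotation_recovers_image(self, random_image):
        img = random_image(3).channels
        twice = np.rot90(np.rot90(img, 2, axes=(1, 2)), 2, axes=(1, 2))
        np.testing.assert_array_equal(img, twice)

    def test_deterministic_under_seed(self, random_image):
        sample = AugmentedSample(image=random_image(4), label_set={"1"})
        a = geometric_colour_transform(sample, 99)
        b = geometric_colour_transform(sample, 99)
        np.testing.assert_array_equal(a.image.channels, b.image.channels)

    def test_nonsquare_frame_preserved(self):
        rng = np.random.default_rng(0)
        sample = AugmentedSample(
            image=MultiChannelImage(rng.uniform(0, 1, (4, 12, 20))),
            label_set={"0"},
        )
        for seed in range(20):
            out = geometric_colour_transform(sample, seed)
            assert out.image.channels.shape == (4, 12, 20)


class TestMixupMatrix:
    def test_bounds(self):
        lam = sample_mixup_matrix(50, 50, 0)
        assert lam.values.min() >= 0.35
        assert lam.values.max() <= 0.65

    def test_deterministic(self):
        a = sample_mixup_matrix(8, 8, 123)
        b = sample_mixup_matrix(8, 8, 123)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_mean_of_uniform(self):
        lam = sample_mixup_matrix(1000, 1000, 7)
        # mean of U(0.35, 0.65) is 0.5, sd = 0.3/sqrt(12)
        se = (0.3 / np.sqrt(12)) / 1000.0
        assert abs(lam.values.mean() - 0.5) < 3 * se

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            sample_mixup_matrix(0, 5, 0)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            MixupCoefficientMatrix(values=np.full((2, 2), 0.7))


class TestMatrixMixup:
    def test_self_mixup_is_identity(self, sample_pair):
        a, _ = sample_pair
        lam = sample_mixup_matrix(16, 16, 0)
        out = matrix_mixup(a, a, lam)
        np.testing.assert_allclose(out.image.channels, a.image.channels, atol=1e-15)

    def test_halfway_point(self, random_image):
        a = AugmentedSample(image=MultiChannelImage(np.full((4, 2, 2), 0.2)), label_set={"1"})
        b = AugmentedSample(image=MultiChannelImage(np.full((4, 2, 2), 0.6)), label_set={"1"})
        lam = MixupCoefficientMatrix(np.full((2, 2), 0.5))
        out = matrix_mixup(a, b, lam)
        np.testing.assert_allclose(out.image.channels, 0.4)

    def test_label_intersection(self, sample_pair):
        a, b = sample_pair
        out = matrix_mixup(a, b, sample_mixup_matrix(16, 16, 1))
        assert out.label_set == frozenset({"8"})

    def test_empty_intersection_rejected(self, random_image):
        a = AugmentedSample(image=random_image(1), label_set={"1"})
        b = AugmentedSample(image=random_image(2), label_set={"2"})
        with pytest.raises(ValueError, match="intersection"):
            matrix_mixup(a, b, sample_mixup_matrix(16, 16, 0))

    def test_swap_symmetry(self, sample_pair):
        a, b = sample_pair
        lam = sample_mixup_matrix(16, 16, 3)
        flipped = MixupCoefficientMatrix(1.0 - lam.values, low=0.35, high=0.65)
        ab = matrix_mixup(a, b, lam)
        ba = matrix_mixup(b, a, flipped)
        np.testing.assert_allclose(ab.image.channels, ba.image.channels, atol=1e-12)

    def test_convex_closure(self, sample_pair):
        a, b = sample_pair
        out = matrix_mixup(a, b, sample_mixup_matrix(16, 16, 5))
        assert out.image.channels.min() >= 0.0
        assert out.image.channels.max() <= 1.0

    def test_dimension_mismatch_rejected(self, sample_pair, random_image):
        a, _ = sample_pair
        small = AugmentedSample(image=random_image(0, size=8), label_set={"8"})
        with pytest.raises(ValueError, match="mismatch"):
            matrix_mixup(a, small, sample_mixup_matrix(16, 16, 0))


class TestRotationMatrix:
    def test_printed_forms(self):
        t = np.deg2rad(33.0)
        c, s = np.cos(t), np.sin(t)
        np.testing.assert_allclose(
            rotation_matrix("G", 33.0),
            [[c, 0, s], [0, 1, 0], [-s, 0, c]],
        )
        np.testing.assert_allclose(
            rotation_matrix("R", 33.0),
            [[1, 0, 0], [0, c, -s], [0, s, c]],
        )

    def test_zero_angle_is_identity(self):
        for axis in ("G", "R"):
            np.testing.assert_allclose(rotation_matrix(axis, 0.0), np.eye(3))

    @settings(derandomize=True, max_examples=100)
    @given(
        theta=st.floats(-720, 720, allow_nan=False),
        axis=st.sampled_from(["G", "R"]),
    )
    def test_orthonormal_unit_determinant(self, theta, axis):
        R = rotation_matrix(axis, theta)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_inverse_is_negative_angle(self):
        for axis in ("G", "R"):
            R = rotation_matrix(axis, 47.0) @ rotation_matrix(axis, -47.0)
            np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_green_axis_quarter_turn(self):
        out = np.array([1.0, 0.5, 0.0]) @ rotation_matrix("G", 90.0)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0], atol=1e-12)


class TestRotateColourSpace:
    def test_zero_angle_unchanged(self, random_image):
        img = random_image(0)
        out = rotate_colour_space(img, "G", 0.0)
        np.testing.assert_allclose(out.channels, img.channels, atol=1e-15)

    def test_axis_channel_bit_identical(self, random_image):
        img = random_image(1)
        assert np.array_equal(
            rotate_colour_space(img, "G", 95.0).channels[1], img.channels[1]
        )
        assert np.array_equal(
            rotate_colour_space(img, "R", 200.0).channels[0], img.channels[0]
        )

    def test_blue_channel_passthrough(self, random_image):
        img = random_image(2)
        for axis in ("G", "R"):
            out = rotate_colour_space(img, axis, 140.0)
            assert np.array_equal(out.channels[2], img.channels[2])

    def test_preclip_norm_preserved(self, random_image):
        img = random_image(3, high=0.5)
        for axis, theta in (("G", 60.0), ("R", 250.0)):
            raw = rotate_colour_space(img, axis, theta, clip=False)
            pre = np.sqrt(
                img.channels[0] ** 2 + img.channels[1] ** 2 + img.channels[3] ** 2
            )
            post = np.sqrt(raw[0] ** 2 + raw[1] ** 2 + raw[3] ** 2)
            np.testing.assert_allclose(pre, post, atol=1e-9)

    def test_quarter_turn_pixel(self):
        img = MultiChannelImage(
            np.stack(
                [
                    np.full((1, 1), 1.0),  # red
                    np.full((1, 1), 0.5),  # green
                    np.zeros((1, 1)),  # blue
                    np.zeros((1, 1)),  # yellow
                ]
            )
        )
        out = rotate_colour_space(img, "G", 90.0)
        np.testing.assert_allclose(
            out.channels[:, 0, 0], [0.0, 0.5, 0.0, 1.0], atol=1e-12
        )

    def test_output_clipped_to_unit_interval(self, random_image):
        img = random_image(4)
        for theta in (60.0, 110.0, 150.0, 250.0, 300.0):
            out = rotate_colour_space(img, "G", theta)
            assert out.channels.min() >= 0.0
            assert out.channels.max() <= 1.0


class TestThetaSampler:
    @staticmethod
    def _which_set(theta):
        if 60.0 <= theta <= 110.0:
            return "A"
        if 120.0 <= theta <= 300.0:
            return "B"
        return None

    def test_strict_alternation(self):
        sampler = ThetaSampler(seed=17)
        sets = [self._which_set(sampler.draw()) for _ in range(10_000)]
        assert None not in sets
        assert all(a != b for a, b in zip(sets, sets[1:]))

    def test_both_starting_sets_occur(self):
        starts = {self._which_set(ThetaSampler(seed=s).draw()) for s in range(20)}
        assert starts == {"A", "B"}


class TestNonlinearMixup:
    def test_green_axis_preserves_mixup_green(self, sample_pair):
        a, b = sample_pair
        out = nonlinear_mixup(a, b, "G", ThetaSampler(0), seed=5)
        lam = sample_mixup_matrix(16, 16, 5)
        mix = matrix_mixup(a, b, lam)
        assert np.array_equal(out.image.channels[1], mix.image.channels[1])

    def test_red_axis_preserves_mixup_red(self, sample_pair):
        a, b = sample_pair
        out = nonlinear_mixup(a, b, "R", ThetaSampler(0), seed=5)
        lam = sample_mixup_matrix(16, 16, 5)
        mix = matrix_mixup(a, b, lam)
        assert np.array_equal(out.image.channels[0], mix.image.channels[0])

    def test_label_inheritance_and_provenance(self, sample_pair):
        a, b = sample_pair
        out = nonlinear_mixup(a, b, "G", ThetaSampler(1), seed=9)
        assert out.label_set == frozenset({"8"})
        assert out.provenance["operator"] == "NLmixupG"
        assert out.provenance["parents"] == ("a", "b")
        assert 60.0 <= out.provenance["theta"] <= 300.0

    def test_consecutive_thetas_from_different_sets(self, sample_pair):
        a, b = sample_pair
        sampler = ThetaSampler(3)
        t1 = nonlinear_mixup(a, b, "G", sampler, 0).provenance["theta"]
        t2 = nonlinear_mixup(a, b, "R", sampler, 1).provenance["theta"]
        in_a = lambda t: 60.0 <= t <= 110.0
        assert in_a(t1) != in_a(t2)


class TestMaterializeRecord:
    def test_roundtrip_reproduces_recorded_theta(self, sample_pair):
        a, b = sample_pair
        store = {"a": a, "b": b}
        record = SupplementRecord("8", "NLmixupG", ("a", "b"), theta=97.5)
        out1 = materialize_record(record, store.__getitem__, seed=4)
        out2 = materialize_record(record, store.__getitem__, seed=4)
        np.testing.assert_array_equal(out1.image.channels, out2.image.channels)
        assert out1.provenance["theta"] == 97.5

    def test_gct_record(self, sample_pair):
        a, _ = sample_pair
        record = SupplementRecord("8", "GCT", ("a",))
        out = materialize_record(record, {"a": a}.__getitem__, seed=2)
        assert out.provenance["operator"] == "GCT"
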