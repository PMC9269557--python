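"""Augmentation operators and the 48x schema."""

import itertools

import numpy as np
import pandas as pd
import pytest
from PIL import Image

import octlite as ol
from octlite.augment import (
    AugmentationOp,
    AugmentationSchema,
    apply_schema,
    augment_dataset,
    change_aspect,
    default_schema,
    default_sigma,
    equalize_histogram,
    expected_augmented_counts,
    gaussian_blur,
    make_gaussian_kernel,
    mirror_horizontal,
    rotate,
    sharpen,
)


class TestMirror:
    def test_reverses_columns(self):
        img = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        assert np.array_equal(mirror_horizontal(img), [[2, 1], [4, 3]])

    def test_involution_on_speckle(self, speckle_image):
        assert np.array_equal(
            mirror_horizontal(mirror_horizontal(speckle_image)), speckle_image
        )

    def test_single_column_unchanged(self):
        img = np.arange(5, dtype=np.uint8).reshape(5, 1)
        assert np.array_equal(mirror_horizontal(img), img)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mirror_horizontal(np.empty((0, 3), dtype=np.uint8))


class TestRotate:
    def test_zero_is_identity(self, speckle_image):
        assert np.array_equal(rotate(speckle_image, 0), speckle_image)

    def test_shape_preserved(self, speckle_image):
        for a in (-15, -10, -5, 5, 10, 15):
            assert rotate(speckle_image, a).shape == speckle_image.shape

    def test_positive_angle_is_clockwise(self):
        # A bright pixel at top-center moves toward the right under a
        # clockwise rotation (viewing row 0 as the top of the image).
        img = np.zeros((33, 33), dtype=np.uint8)
        img[4, 16] = 255
        out = rotate(img, 15)
        r, c = np.unravel_index(np.argmax(out), out.shape)
        assert c > 16

    def test_inverse_rotation_recovers_center(self, speckle_image):
        """rotate(+10) then rotate(-10) restores the central half within a
        mean absolute error of 2 intensity levels on a smooth fixture.

        (Bilinear resampling cannot reconstruct content at the pixel scale,
        so the fixture is a smoothed scan rather than raw speckle.)"""
        smooth = gaussian_blur(
            gaussian_blur(speckle_image, (9, 9), sigma=2.5), (9, 9), sigma=2.5
        )
        back = rotate(rotate(smooth, 10), -10)
        h, w = smooth.shape
        sl = np.s_[h // 4 : 3 * h // 4, w // 4 : 3 * w // 4]
        mae = np.abs(back[sl].astype(float) - smooth[sl].astype(float)).mean()
        assert mae <= 2.0

    def test_symmetric_disk_invariant_center(self):
        h = w = 65
        rr, cc = np.mgrid[:h, :w]
        disk = (((rr - 32) ** 2 + (cc - 32) ** 2) <= 20**2).astype(np.uint8) * 200
        out = rotate(disk, 15)
        sl = np.s_[22:43, 22:43]
        assert np.abs(out[sl].astype(float) - disk[sl].astype(float)).max() <= 3

    def test_disallowed_angle(self, speckle_image):
        with pytest.raises(ValueError):
            rotate(speckle_image, 7)
        with pytest.raises(ValueError):
            rotate(speckle_image, 20)


class TestAspect:
    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 77, dtype=np.uint8)
        assert np.array_equal(change_aspect(img, 1.30, 1.0), img)

    def test_output_shape_equals_input_shape(self, speckle_image):
        for sx, sy in [(1.05, 1.0), (1.30, 1.0), (1.0, 1.15), (1.15, 1.15)]:
            assert change_aspect(speckle_image, sx, sy).shape == speckle_image.shape

    def test_stripe_period_scales(self):
        """Stretching x by 1.30 should stretch a vertical-stripe period from
        8 to about 10.4 pixels, measured by autocorrelation."""
        img = ((np.arange(128) // 4) % 2 * 255).astype(np.uint8)
        img = np.tile(img, (64, 1))
        out = change_aspect(img, 1.30, 1.0).astype(float)
        row = out.mean(axis=0) - out.mean()

        def dominant_period(sig):
            ac = np.correlate(sig, sig, mode="full")[len(sig) - 1 :]
            # first local max after lag 2
            for lag in range(2, len(ac) - 1):
                if ac[lag] >= ac[lag - 1] and ac[lag] > ac[lag + 1]:
                    return lag
            return None

        assert abs(dominant_period(row) - 10.4) <= 1.0

    def test_invalid_scales_rejected(self, speckle_image):
        for sx, sy in [(1.02, 1.0), (1.5, 1.0), (0.9, 1.1), (1.0, 1.0)]:
            with pytest.raises(ValueError):
                change_aspect(speckle_image, sx, sy)


class TestEqualize:
    def test_constant_image_stays_constant(self):
        img = np.full((16, 16), 99, dtype=np.uint8)
        out = equalize_histogram(img)
        assert len(np.unique(out)) == 1

    def test_two_level_image_spans_range(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        out = equalize_histogram(img)
        assert out.min() <= out[img == 0].max() < out[img == 255].min() == 255

    def test_mapping_is_monotone(self, speckle_image):
        out = equalize_histogram(speckle_image)
        pairs = sorted(
            {(int(a), int(b)) for a, b in zip(speckle_image.ravel(), out.ravel())}
        )
        values = [b for _, b in pairs]
        assert values == sorted(values)

    def test_histogram_flattens(self, speckle_image):
        """The 16-bin histogram's coefficient of variation must not grow."""
        def cv(img):
            counts, _ = np.histogram(img, bins=16, range=(0, 256))
            return counts.std() / counts.mean()

        assert cv(equalize_histogram(speckle_image)) <= cv(speckle_image) + 1e-12

    def test_three_channel_replicated(self, speckle_image):
        stacked = np.repeat(speckle_image[..., None], 3, axis=2)
        out = equalize_histogram(stacked)
        assert out.shape == stacked.shape
        assert np.array_equal(out[..., 0], out[..., 2])


class TestGaussianKernel:
    @pytest.mark.parametrize("size,sigma", [(3, 0.5), (5, 1.1), (7, 2.0), (9, 0.8)])
    def test_normalized_symmetric_unimodal(self, size, sigma):
        k = make_gaussian_kernel(size, sigma)
        e = k.entries
        assert abs(e.sum() - 1.0) <= 1e-12
        assert np.allclose(e, e[::-1, :]) and np.allclose(e, e[:, ::-1])
        assert e.max() == e[size // 2, size // 2]
        assert (e > 0).all()

    def test_large_sigma_approaches_uniform(self):
        e = make_gaussian_kernel(3, 1e6).entries
        assert np.allclose(e, 1.0 / 9.0, atol=1e-9)

    def test_default_sigma_rule(self):
        assert default_sigma(5) == pytest.approx(1.1)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            make_gaussian_kernel(4)
        with pytest.raises(ValueError):
            make_gaussian_kernel(5, sigma=0.0)


class TestBlur:
    def test_constant_preserved(self):
        img = np.full((20, 20), 123, dtype=np.uint8)
        assert np.array_equal(gaussian_blur(img), img)

    def test_variance_never_increases(self, speckle_image):
        assert gaussian_blur(speckle_image).astype(float).var() <= (
            speckle_image.astype(float).var()
        )

    def test_impulse_response_is_the_kernel(self):
        """An interior bright pixel spreads into exactly the normalized
        kernel scaled by its intensity — a direct convolution oracle."""
        img = np.zeros((11, 11), dtype=np.uint8)
        img[5, 5] = 255
        out = gaussian_blur(img)
        expected = np.rint(make_gaussian_kernel(5).entries * 255)
        assert np.array_equal(out[3:8, 3:8].astype(float), expected)
        assert out[:2].sum() == 0  # nothing beyond the kernel footprint


class TestSharpen:
    def test_constant_preserved(self):
        img = np.full((12, 12), 44, dtype=np.uint8)
        assert np.array_equal(sharpen(img), img)

    def test_isolated_pixel_hand_convolution(self):
        # center value before clipping: 9*10 = 90; neighbors: -10 -> 0
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 10
        out = sharpen(img)
        assert out[4, 4] == 90
        assert out[4, 3] == 0 and out[3, 3] == 0

    def test_step_edge_overshoot_clips(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        out = sharpen(img)
        # 255 side adjacent to the edge overshoots (clips at 255); the dark
        # side undershoots (clips at 0).
        assert (out[:, 5] == 255).all()
        assert (out[:, 4] == 0).all()


class TestSchema:
    def test_default_multiplicity_is_48(self):
        assert default_schema().multiplicity == 48

    def test_apply_schema_emits_48_shape_preserving_outputs(self, speckle_image):
        outs = apply_schema(speckle_image, default_schema())
        assert len(outs) == 48
        assert all(o.shape == speckle_image.shape for o in outs)

    def test_outputs_pairwise_distinct_on_speckle(self, speckle_image):
        outs = apply_schema(speckle_image, default_schema())
        for a, b in itertools.combinations(range(48), 2):
            assert not np.array_equal(outs[a], outs[b])

    def test_single_identity_stage_returns_input(self, speckle_image):
        schema = AugmentationSchema(stages=((AugmentationOp("identity"),),))
        outs = apply_schema(speckle_image, schema)
        assert len(outs) == 1
        assert np.array_equal(outs[0], speckle_image)

    def test_deterministic_across_runs(self, speckle_image):
        a = apply_schema(speckle_image, default_schema())
        b = apply_schema(speckle_image, default_schema())
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSchema(stages=((),))


class TestAugmentDataset:
    def test_materialized_counts(self, tmp_path):
        spec = ol.SyntheticSpec(image_height=48, image_width=48, n_per_class=10, seed=9)
        manifest = ol.write_dataset(spec, tmp_path / "in", (10, 0, 0))
        cnv_only = manifest[manifest["label"] == "CNV"]
        counts = augment_dataset(cnv_only, default_schema(), tmp_path / "out")
        row = counts[counts["Category"] == "CNV"].iloc[0]
        assert row["Original"] == 10 and row["Augmented"] == 480
        assert len(list((tmp_path / "out" / "CNV").glob("*.jpeg"))) == 480
        # classes with no inputs: zero counts, no directory error
        dme = counts[counts["Category"] == "DME"].iloc[0]
        assert dme["Original"] == 0 and dme["Augmented"] == 0

    def test_filename_convention(self, tmp_path):
        spec = ol.SyntheticSpec(image_height=48, image_width=48, n_per_class=1, seed=9)
        manifest = ol.write_dataset(spec, tmp_path / "in", (1, 0, 0))
        one = manifest[manifest["label"] == "DME"]
        augment_dataset(one, default_schema(), tmp_path / "out")
        names = sorted(p.name for p in (tmp_path / "out" / "DME").glob("*.jpeg"))
        assert names[0] == "DME-00000__m0_g0_p0.jpeg"
        assert names[-1] == "DME-00000__m1_g7_p2.jpeg"

    def test_strict_mode_fails_on_unreadable(self, tmp_path):
        bad = tmp_path / "bad.jpeg"
        bad.write_bytes(b"not a jpeg")
        manifest = pd.DataFrame({"path": [str(bad)], "label": ["CNV"]})
        with pytest.raises(RuntimeError):
            augment_dataset(manifest, default_schema(), tmp_path / "out", strict=True)
        counts = augment_dataset(
            manifest, default_schema(), tmp_path / "out", strict=False
        )
        assert counts["Augmented"].sum() == 0


def test_counting_rule_reproduces_published_totals():
    """Applying the 48x counting rule to the published per-class originals
    (37,205 / 11,348 / 8,616 / 26,315) yields the published augmented
    column — pure arithmetic, nothing materialized."""
    got = expected_augmented_counts([37205, 11348, 8616, 26315])
    assert got == [1785840, 544704, 413568, 1263120]
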