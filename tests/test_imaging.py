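"""Cell-pixel pipeline: each step against an independent oracle, plus
composition and monotonicity properties."""

import numpy as np
import pytest

from cellflux.imaging import (
    ImageError,
    ImagingParams,
    correct_and_invert,
    count_cell_pixels,
    crop_margins,
    estimate_background,
    quantify_well,
    read_image,
    read_pixel_table,
    to_grayscale,
    well_id_from_filename,
    write_pixel_table,
)
from cellflux.synthdata import ImageSynthParams, synth_well_image


# ---------------------------------------------------------------------------
# to_grayscale


class TestToGrayscale:
    def test_identity_on_canonical_scale(self, random_gray):
        np.testing.assert_array_equal(to_grayscale(random_gray), random_gray)

    def test_three_channel_mean(self):
        img = np.full((20, 20, 3), 100, dtype=np.float64)
        np.testing.assert_array_equal(to_grayscale(img), np.full((20, 20), 100.0))

    def test_16bit_rescale_matches_per_pixel_loop(self, rng):
        img = rng.integers(0, 65536, size=(20, 24), dtype=np.uint16)
        img.flat[0] = 65535  # pin the max so full scale maps to 255
        out = to_grayscale(img)
        expected = np.empty(img.shape)
        for i in range(img.shape[0]):  # independent per-pixel rescale
            for j in range(img.shape[1]):
                expected[i, j] = img[i, j] * 255.0 / 65535.0
        np.testing.assert_allclose(out, expected, rtol=0, atol=1e-12)
        assert out.max() == pytest.approx(255.0)

    def test_unit_scale_float_rescaled(self):
        img = np.linspace(0, 1, 400).reshape(20, 20)
        assert to_grayscale(img).max() == pytest.approx(255.0)

    @pytest.mark.parametrize(
        "bad",
        [
            np.zeros((20, 20, 4)),
            np.zeros((8, 8)),
            np.full((20, 20), np.nan),
        ],
        ids=["four-channel", "too-small", "non-finite"],
    )
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ImageError):
            to_grayscale(bad)


# ---------------------------------------------------------------------------
# estimate_background


def _gaussian_blur_loops(image, sigma, truncate=4.0):
    """Direct separable discrete Gaussian convolution with replicated
    edges, written as explicit loops — the oracle for the library call."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    h, w = image.shape
    tmp = np.zeros_like(image)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for t, kv in zip(x, kernel):
                acc += kv * image[i, min(max(j - t, 0), w - 1)]
            tmp[i, j] = acc
    out = np.zeros_like(image)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for t, kv in zip(x, kernel):
                acc += kv * tmp[min(max(i - t, 0), h - 1), j]
            out[i, j] = acc
    return out


class TestEstimateBackground:
    def test_constant_preserved(self):
        img = np.full((32, 32), 80.0)
        np.testing.assert_allclose(estimate_background(img, 5.0), img, atol=1e-9)

    def test_matches_direct_convolution_on_point_source(self):
        img = np.zeros((33, 33))
        img[16, 16] = 200.0
        sigma = 2.5
        np.testing.assert_allclose(
            estimate_background(img, sigma),
            _gaussian_blur_loops(img, sigma),
            atol=1e-10,
        )

    def test_linear_gradient_fixed_away_from_edges(self):
        w = 64
        img = np.tile(np.linspace(0, 200, w), (64, 1))
        blurred = estimate_background(img, w / 10)
        interior = slice(w // 2 - 4, w // 2 + 4)
        assert np.max(np.abs(blurred[:, interior] - img[:, interior])) < 1.0

    def test_rejects_nonpositive_sigma(self, random_gray):
        with pytest.raises(ImageError):
            estimate_background(random_gray, 0.0)


# ---------------------------------------------------------------------------
# correct_and_invert


class TestCorrectAndInvert:
    def test_exact_cancellation(self, random_gray):
        out = correct_and_invert(random_gray, random_gray)
        np.testing.assert_array_equal(out, np.zeros_like(random_gray))

    def test_definition_with_clipping(self):
        bg = np.full((16, 16), 100.0)
        img = np.full((16, 16), 60.0)
        img[0, 0] = 130.0
        out = correct_and_invert(img, bg)
        assert out[1, 1] == 40.0
        assert out[0, 0] == 0.0

    def test_matches_per_pixel_loop(self, rng, random_gray):
        bg = estimate_background(random_gray, 4.0)
        out = correct_and_invert(random_gray, bg)
        expected = np.empty_like(random_gray)
        for i in range(random_gray.shape[0]):
            for j in range(random_gray.shape[1]):
                expected[i, j] = max(bg[i, j] - random_gray[i, j], 0.0)
        np.testing.assert_array_equal(out, expected)

    def test_equivalent_to_subtract_negate_clip(self, rng, random_gray):
        # subtract background, negate, clip — the two-step formulation
        bg = estimate_background(random_gray, 4.0)
        two_step = np.clip(-(random_gray - bg), 0.0, 255.0)
        np.testing.assert_array_equal(correct_and_invert(random_gray, bg), two_step)

    def test_dimension_mismatch(self, random_gray):
        with pytest.raises(ImageError):
            correct_and_invert(random_gray, np.zeros((16, 16)))


# ---------------------------------------------------------------------------
# crop_margins


class TestCropMargins:
    @pytest.mark.parametrize(
        "shape,fraction,expected",
        [
            ((200, 200), 0.05, (180, 180)),
            ((200, 200), 0.0, (200, 200)),
            ((101, 63), 0.05, (91, 57)),
            ((64, 48), 0.25, (32, 24)),
            ((17, 17), 0.05, (17, 17)),
        ],
    )
    def test_floor_formula(self, shape, fraction, expected):
        out = crop_margins(np.zeros(shape), fraction)
        assert out.shape == expected

    def test_identity_preserves_values(self, random_gray):
        np.testing.assert_array_equal(crop_margins(random_gray, 0.0), random_gray)

    def test_keeps_central_region(self):
        img = np.arange(400, dtype=float).reshape(20, 20)
        out = crop_margins(img, 0.05)
        np.testing.assert_array_equal(out, img[1:19, 1:19])

    @pytest.mark.parametrize("fraction", [-0.01, 0.5, 1.0])
    def test_rejects_bad_fraction(self, random_gray, fraction):
        with pytest.raises(ImageError):
            crop_margins(random_gray, fraction)


# ---------------------------------------------------------------------------
# count_cell_pixels


class TestCountCellPixels:
    def test_all_zero(self):
        assert count_cell_pixels(np.zeros((30, 30)), 1.0) == 0

    def test_exact_count(self, rng):
        img = np.zeros((40, 40))
        idx = rng.choice(1600, size=37, replace=False)
        img.flat[idx] = 10.0
        assert count_cell_pixels(img, 1.0) == 37

    def test_strictly_greater(self):
        img = np.full((16, 16), 1.0)
        assert count_cell_pixels(img, 1.0) == 0
        assert count_cell_pixels(img, 0.999) == 256

    def test_matches_scan_loop_on_random_images(self, rng):
        for _ in range(50):
            img = rng.uniform(0, 5, size=(24, 24))
            thr = rng.uniform(0, 5)
            scan = sum(
                1
                for i in range(img.shape[0])
                for j in range(img.shape[1])
                if img[i, j] > thr
            )
            assert count_cell_pixels(img, thr) == scan

    def test_monotone_nonincreasing_in_threshold(self, random_gray):
        thresholds = np.linspace(0, 255, 20)
        counts = [count_cell_pixels(random_gray, t) for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# quantify_well


def _stepwise(image, params):
    gray = to_grayscale(image)
    bg = estimate_background(gray, params.sigma_for(gray.shape))
    corrected = correct_and_invert(gray, bg)
    cropped = crop_margins(corrected, params.crop_fraction)
    return count_cell_pixels(cropped, params.threshold)


class TestQuantifyWell:
    def test_constant_image_yields_zero(self, rng):
        for level in rng.uniform(0, 255, size=10):
            img = np.full((40, 40), level)
            assert quantify_well(img).count == 0

    def test_composition_equals_stepwise(self, rng):
        params = ImagingParams()
        for seed in range(5):
            img, _ = synth_well_image(ImageSynthParams(shape=(96, 96), n_cells=30, seed=seed))
            assert quantify_well(img, params).count == _stepwise(img, params)

    def test_disks_yield_expected_pixel_scale(self):
        # 100 disks of radius 3, depth 60: the pipeline count should land
        # within 10% of the stepwise reference on the same image
        params = ImagingParams()
        img, _ = synth_well_image(
            ImageSynthParams(
                shape=(256, 256), n_cells=100, radius_range=(3.0, 3.0),
                darkness=60.0, noise_sd=0.0, seed=7,
            )
        )
        count = quantify_well(img, params).count
        reference = _stepwise(img, params)
        assert count == reference
        # and the count is commensurate with 100 rendered disks
        per_disk = count / 100
        assert 10 < per_disk < 80

    def test_denser_well_counts_more(self):
        lo, _ = synth_well_image(ImageSynthParams(shape=(192, 192), n_cells=40, seed=11))
        hi, _ = synth_well_image(ImageSynthParams(shape=(192, 192), n_cells=240, seed=11))
        assert quantify_well(hi).count > quantify_well(lo).count

    def test_mean_count_increasing_across_densities(self):
        # area-scaled analogues of 25k..150k cells/well
        densities = [25, 50, 100, 150]
        means = []
        for n in densities:
            counts = [
                quantify_well(
                    synth_well_image(ImageSynthParams(shape=(128, 128), n_cells=n, seed=s))[0]
                ).count
                for s in range(10)
            ]
            means.append(np.mean(counts))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_params_hash_tracks_parameters(self):
        img, _ = synth_well_image(ImageSynthParams(shape=(64, 64), n_cells=10, seed=0))
        h1 = quantify_well(img, ImagingParams()).params_hash
        h2 = quantify_well(img, ImagingParams(threshold=2.0)).params_hash
        assert h1 != h2
        assert quantify_well(img, ImagingParams()).params_hash == h1


# ---------------------------------------------------------------------------
# file IO


class TestImagingIO:
    @pytest.mark.parametrize(
        "name,expected",
        [("B07.png", "B07"), ("plate3_A1.tif", "A01"), ("xH12.png", "H12")],
    )
    def test_well_id_from_filename(self, name, expected):
        assert well_id_from_filename(name) == expected

    def test_well_id_rejects_garbage(self):
        with pytest.raises(ImageError):
            well_id_from_filename("notawell.png")

    def test_png_and_tiff_round_trip(self, tmp_path):
        img, _ = synth_well_image(ImageSynthParams(shape=(64, 64), n_cells=20, seed=3))
        arr = np.round(img).astype(np.uint8)

        from PIL import Image
        import tifffile

        Image.fromarray(arr).save(tmp_path / "A01.png")
        tifffile.imwrite(tmp_path / "A02.tif", arr)
        np.testing.assert_array_equal(read_image(tmp_path / "A01.png"), arr)
        np.testing.assert_array_equal(read_image(tmp_path / "A02.tif"), arr)

    def test_pixel_table_round_trip(self, tmp_path):
        img, _ = synth_well_image(ImageSynthParams(shape=(64, 64), n_cells=20, seed=3))
        counts = [quantify_well(img, well_id=w) for w in ("A01", "B07")]
        path = tmp_path / "pixels.csv"
        write_pixel_table(counts, path, plate_id="p1")
        df = read_pixel_table(path)
        assert list(df["well"]) == ["A01", "B07"]
        assert list(df["cell_pixels"]) == [c.count for c in counts]
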