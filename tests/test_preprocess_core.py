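import numpy as np
import pytest

from lungprep import (
    BinaryMask,
    RawImage,
    StructuringElement,
    binarize_lungs,
    clear_outside_body,
    dilate,
    enhance_contrast,
    erode,
    fill_holes,
    identify_body,
    normalize_image,
    otsu_threshold,
    refine_morphology,
    remove_small_objects,
    segment_slice,
)
from lungprep.errors import NoBodyError, ValidationError
from lungprep.preprocess_core import NormalizedImage, close

from conftest import mask, random_mask

SE5 = StructuringElement.square(5)


def brute_force_otsu(values: np.ndarray, bins: int = 256):
    """Independent oracle: plain-python scan of all internal bin-edge cuts."""
    counts, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    total = counts.sum()
    best_k, best_sigma = None, -1.0
    for k in range(1, bins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        centers = (np.arange(bins) + 0.5) / bins
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        sigma = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if sigma > best_sigma + 1e-15:  # strict improvement: ties keep smaller k
            best_k, best_sigma = k, sigma
    return best_k / bins, best_sigma


class TestNormalize:
    def test_exact_fractions(self):
        out = normalize_image(RawImage(np.array([[0, 50], [100, 200]])))
        assert out.pixels.tolist() == [[0.0, 0.25], [0.5, 1.0]]

    def test_constant_image_all_zeros(self, caplog):
        out = normalize_image(RawImage(np.full((2, 2), 7)))
        assert (out.pixels == 0).all()

    def test_idempotent_on_unit_range(self, rng):
        arr = rng.random((16, 16))
        arr[0, 0], arr[0, 1] = 0.0, 1.0
        out = normalize_image(RawImage(arr))
        np.testing.assert_allclose(out.pixels, arr)

    def test_minmax_exact(self, rng):
        out = normalize_image(RawImage(rng.integers(3, 250, (20, 20))))
        assert out.pixels.min() == 0.0 and out.pixels.max() == 1.0


class TestEnhanceContrast:
    def test_identity_stretch(self):
        ramp = NormalizedImage(np.linspace(0, 1, 101).reshape(1, -1))
        out = enhance_contrast(ramp, 0, 100)
        np.testing.assert_allclose(out.pixels, ramp.pixels)

    def test_ramp_quartile_stretch(self):
        # ramp 0..1: p25 = 0.25, p75 = 0.75 exactly (101 samples)
        ramp = NormalizedImage(np.linspace(0, 1, 101).reshape(1, -1))
        out = enhance_contrast(ramp, 25, 75).pixels.ravel()
        assert (out[:26] == 0.0).all()
        assert (out[75:] == 1.0).all()
        np.testing.assert_allclose(out[50], 0.5, atol=1e-12)

    def test_bad_percentiles(self):
        with pytest.raises(ValidationError):
            enhance_contrast(NormalizedImage(np.zeros((2, 2))), 50, 50)

    def test_degenerate_returns_input(self, caplog):
        img = NormalizedImage(np.array([[0.0, 0.0, 0.0, 1.0]]))
        out = enhance_contrast(img, 1, 60)  # both percentiles hit 0.0
        np.testing.assert_allclose(out.pixels, img.pixels)


class TestOtsu:
    def test_bimodal_separates(self):
        arr = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)]).reshape(10, 10)
        res = otsu_threshold(NormalizedImage(arr))
        assert 0.1 < res.threshold < 0.9

    @pytest.mark.parametrize("frac", [0.25, 0.75])
    def test_unbalanced_classes_still_separate(self, frac):
        n = 100
        arr = np.concatenate(
            [np.full(int(n * frac), 0.1), np.full(n - int(n * frac), 0.9)]
        ).reshape(10, 10)
        res = otsu_threshold(NormalizedImage(arr))
        assert 0.1 < res.threshold < 0.9

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            arr = rng.random((64, 64))
            res = otsu_threshold(NormalizedImage(arr))
            t_ref, s_ref = brute_force_otsu(arr)
            assert res.threshold == pytest.approx(t_ref, abs=0)
            assert res.between_class_variance == pytest.approx(s_ref, rel=1e-9)

    def test_constant_image_errors(self):
        with pytest.raises(ValidationError):
            otsu_threshold(NormalizedImage(np.full((4, 4), 0.5)))

    def test_histogram_totals(self, rng):
        arr = rng.random((32, 32))
        res = otsu_threshold(NormalizedImage(arr))
        assert res.histogram.sum() == arr.size


class TestBinarize:
    def test_polarity(self):
        out = binarize_lungs(NormalizedImage(np.array([[0.1, 0.9]])), 0.5)
        assert out.pixels.tolist() == [[1, 0]]

    def test_all_above(self):
        out = binarize_lungs(NormalizedImage(np.full((3, 3), 0.8)), 0.5)
        assert not out.pixels.any()

    def test_otsu_recovers_known_classes(self, rng):
        lo = rng.uniform(0.05, 0.15, (16, 16))
        arr = lo.copy()
        arr[8:, :] = rng.uniform(0.7, 0.9, (8, 16))
        res = otsu_threshold(NormalizedImage(arr))
        out = binarize_lungs(NormalizedImage(arr), res.threshold)
        assert out.pixels[:8].all() and not out.pixels[8:].any()


class TestBodyIsolation:
    def test_largest_component_holes_filled(self):
        arr = np.zeros((20, 20), dtype=np.uint8)
        arr[2:14, 2:14] = 1  # big blob with a hole
        arr[6:9, 6:9] = 0
        arr[16:19, 16:19] = 1  # small blob
        body = identify_body(mask(arr))
        expect = np.zeros_like(arr)
        expect[2:14, 2:14] = 1
        assert body.pixels.tolist() == expect.tolist()

    def test_empty_dense_mask_errors(self):
        with pytest.raises(NoBodyError):
            identify_body(mask(np.zeros((5, 5), dtype=np.uint8)))

    def test_phantom_body_recovered(self, small_phantom):
        dense = BinaryMask(
            (small_phantom.image.pixels >= 100).astype(np.uint8)
        )  # tissue is bright
        body = identify_body(dense)
        assert body == small_phantom.body_mask

    def test_clear_outside_body(self):
        cand = mask([[1, 0, 1], [0, 1, 0], [1, 0, 0]])
        body = mask([[0, 0, 0], [0, 1, 1], [0, 1, 1]])
        out = clear_outside_body(cand, body)
        assert out.pixels.tolist() == [[0, 0, 0], [0, 1, 0], [0, 0, 0]]

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            clear_outside_body(mask(np.zeros((2, 2), int)), mask(np.zeros((3, 3), int)))


class TestFillAndRemove:
    def test_ring_becomes_disc(self):
        arr = np.zeros((9, 9), dtype=np.uint8)
        arr[2:7, 2:7] = 1
        arr[4, 4] = 0
        out = fill_holes(mask(arr))
        assert out.pixels[4, 4] == 1

    def test_no_holes_unchanged(self, rng):
        m = random_mask(rng, (16, 16), p=0.2)
        once = fill_holes(m)
        assert fill_holes(once) == once

    def test_fill_idempotent_random(self, rng):
        for _ in range(100):
            m = random_mask(rng, (24, 24))
            once = fill_holes(m)
            assert fill_holes(once) == once

    def test_small_object_cutoff_arithmetic(self):
        arr = np.zeros((512, 512), dtype=np.uint8)
        arr[10:20, 10:20] = 1  # 100 px speck, below 0.001*262144 = 262.1
        arr[100:150, 100:200] = 1  # 5000 px blob
        out = remove_small_objects(mask(arr), 0.001)
        assert not out.pixels[10:20, 10:20].any()
        assert out.pixels[100:150, 100:200].all()

    def test_zero_frac_identity(self, rng):
        m = random_mask(rng)
        assert remove_small_objects(m, 0.0) == m

    def test_all_below_cutoff(self):
        arr = np.zeros((100, 100), dtype=np.uint8)
        arr[0, 0] = 1
        assert not remove_small_objects(mask(arr), 0.5).pixels.any()


class TestMorphology:
    def test_dilate_point_to_block(self):
        arr = np.zeros((9, 9), dtype=np.uint8)
        arr[4, 4] = 1
        out = dilate(mask(arr), SE5)
        expect = np.zeros_like(arr)
        expect[2:7, 2:7] = 1
        assert out.pixels.tolist() == expect.tolist()

    def test_dilate_empty(self):
        assert not dilate(mask(np.zeros((6, 6), int)), SE5).pixels.any()

    def test_erode_block_to_point(self):
        arr = np.zeros((9, 9), dtype=np.uint8)
        arr[2:7, 2:7] = 1
        out = erode(mask(arr), SE5)
        assert out.pixels.sum() == 1 and out.pixels[4, 4] == 1

    def test_extensive_antiextensive(self, rng):
        for _ in range(25):
            m = random_mask(rng, (20, 20))
            d = dilate(m, SE5).pixels
            e = erode(m, SE5).pixels
            assert (d >= m.pixels).all()
            assert (e <= m.pixels).all()

    def test_duality_with_matched_padding(self, rng):
        # erode(m) == crop(~dilate(~pad(m))): pad ring keeps the clipped
        # dilation of the complement from differing inside the crop window
        for _ in range(25):
            m = random_mask(rng, (20, 20))
            padded = np.pad(m.pixels, 2)
            comp = BinaryMask(1 - padded)
            dual = 1 - dilate(comp, SE5).pixels
            assert (dual[2:-2, 2:-2] == erode(m, SE5).pixels).all()

    def test_closing_bridges_small_gap(self):
        arr = np.zeros((11, 20), dtype=np.uint8)
        arr[3:8, 2:9] = 1
        arr[3:8, 11:18] = 1  # 2-px gap at cols 9-10
        out = close(mask(arr), SE5)
        assert out.pixels[5, 9] == 1 and out.pixels[5, 10] == 1

    def test_closing_idempotent_random(self, rng):
        for _ in range(50):
            m = random_mask(rng, (24, 24))
            once = close(m, SE5)
            assert close(once, SE5) == once

    def test_monotone(self, rng):
        for _ in range(10):
            a = random_mask(rng, (16, 16), p=0.3)
            b = BinaryMask(a.pixels | random_mask(rng, (16, 16), p=0.3).pixels)
            assert (dilate(a, SE5).pixels <= dilate(b, SE5).pixels).all()
            assert (erode(a, SE5).pixels <= erode(b, SE5).pixels).all()

    def test_refine_preserves_disc_area(self):
        yy, xx = np.ogrid[:128, :128]
        disc = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2).astype(np.uint8)
        out = refine_morphology(mask(disc))
        change = abs(int(out.pixels.sum()) - int(disc.sum())) / disc.sum()
        assert change < 0.05

    def test_refine_requires_iterations(self, rng):
        with pytest.raises(ValidationError):
            refine_morphology(random_mask(rng), iterations=0)

    def test_even_se_rejected(self):
        with pytest.raises(ValidationError):
            StructuringElement.square(4)


class TestSegmentSlice:
    def test_clean_phantom_high_iou(self, clean_phantom):
        from lungprep import iou

        out = segment_slice(clean_phantom.image)
        assert iou(out, clean_phantom.lung_mask) >= 0.90

    def test_table_artifact_excluded(self):
        from lungprep import PhantomSpec, generate_phantom

        ph = generate_phantom(
            PhantomSpec(seed=3, noise_sigma=0.0, defects=("TABLE_ARTIFACT",))
        )
        out = segment_slice(ph.image)
        table_region = (ph.image.pixels > 170) & ~ph.body_mask.as_bool()
        assert not (out.as_bool() & table_region).any()

    def test_no_body_on_constant_image(self):
        with pytest.raises(NoBodyError):
            segment_slice(RawImage(np.full((64, 64), 9, dtype=np.uint8)))

    def test_deterministic(self, clean_phantom):
        a = segment_slice(clean_phantom.image)
        b = segment_slice(clean_phantom.image)
        assert a == b
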