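import numpy as np
import pytest
from skimage.filters import threshold_otsu as sk_otsu

from pearlseg import preprocess


def brute_force_equalize(img):
    """Independent CDF mapping computed pixel by pixel."""
    a = img.astype(int)
    n = a.size
    cdf = {v: int((a <= v).sum()) for v in np.unique(a)}
    cdf_min = min(cdf.values())
    out = np.zeros_like(a)
    for v, c in cdf.items():
        out[a == v] = round((c - cdf_min) / (n - cdf_min) * 255)
    return out.astype(np.uint8)


def brute_force_otsu(img):
    """Exhaustive scan of all 256 integer thresholds."""
    a = img.ravel().astype(float)
    best_t, best_s = 0, -1.0
    for t in range(1, 256):
        lo, hi = a[a < t], a[a >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        s = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if s > best_s:
            best_s, best_t = s, t
    return best_t


class TestEqualize:
    def test_constant_image_is_noop(self):
        img = np.full((8, 8), 128, dtype=np.uint8)
        assert np.array_equal(preprocess.equalize_histogram(img), img)

    def test_full_range_two_level_unchanged(self):
        img = np.zeros((4, 8), dtype=np.uint8)
        img[:, 4:] = 255
        assert np.array_equal(preprocess.equalize_histogram(img), img)

    def test_ramp_matches_cdf_oracle(self):
        img = (np.arange(16, dtype=np.uint8) * 16).reshape(4, 4)
        assert np.array_equal(preprocess.equalize_histogram(img), brute_force_equalize(img))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess.equalize_histogram(np.zeros((0, 4)))


class TestGaussian:
    def test_constant_invariant(self):
        img = np.full((16, 16), 77, dtype=np.uint8)
        out = preprocess.gaussian_smooth(img, sigma=1.5)
        assert np.allclose(out, 77.0)

    def test_impulse_peak_matches_kernel(self):
        # independent oracle: sampled, truncated, normalized Gaussian kernel
        sigma = 1.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        img = np.zeros((21, 21), dtype=np.uint8)
        img[10, 10] = 255
        out = preprocess.gaussian_smooth(img, sigma=sigma)
        assert out[10, 10] == pytest.approx(255 * k1[radius] ** 2, rel=1e-10)

    def test_intensity_sum_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        out = preprocess.gaussian_smooth(img, sigma=2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            preprocess.gaussian_smooth(np.zeros((4, 4), dtype=np.uint8), sigma=0)


class TestOtsu:
    def test_bimodal_perfectly_separated(self):
        img = np.full((10, 10), 220, dtype=np.uint8)
        img[:5] = 20
        mask = preprocess.binarize_otsu(img)
        assert mask[:5].all() and not mask[5:].any()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        if seed % 2:
            img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        else:  # bimodal with spread, closer to real backlit histograms
            img = np.where(
                rng.random((24, 24)) < 0.3,
                rng.normal(40, 10, (24, 24)),
                rng.normal(210, 10, (24, 24)),
            )
            img = np.clip(img, 0, 255).astype(np.uint8)
        assert preprocess.otsu_threshold(img) == brute_force_otsu(img)

    def test_agrees_with_skimage_on_bimodal(self):
        rng = np.random.default_rng(7)
        img = np.where(
            rng.random((50, 50)) < 0.4,
            rng.normal(30, 8, (50, 50)),
            rng.normal(220, 8, (50, 50)),
        )
        img = np.clip(img, 0, 255).astype(np.uint8)
        ours = preprocess.binarize_otsu(img)
        theirs = img <= sk_otsu(img)
        assert np.array_equal(ours, theirs)

    def test_recovers_generator_foreground(self, pair_scene):
        img, truth = pair_scene
        mask = preprocess.morphological_clean(
            preprocess.binarize_otsu(
                preprocess.gaussian_smooth(preprocess.equalize_histogram(img))
            )
        )
        true_fg = truth.labels > 0
        from scipy.ndimage import binary_dilation

        eight = np.ones((3, 3), dtype=bool)
        band = binary_dilation(true_fg, eight) & binary_dilation(~true_fg, eight)
        # outside a 1-px boundary band, the recovered mask equals the truth
        core = ~band
        assert np.array_equal(mask[core], true_fg[core])


class TestMorphologicalClean:
    def test_fills_interior_hole(self, make_disc):
        m = make_disc((60, 60), (30, 30), 20)
        holey = m.copy()
        holey[30:32, 30:32] = False
        out = preprocess.morphological_clean(holey, 3)
        assert out[30:32, 30:32].all()
        assert (out ^ m).sum() <= 0.02 * m.sum()  # boundary moved at most slightly

    def test_all_false_stays_empty(self):
        m = np.zeros((10, 10), dtype=bool)
        assert not preprocess.morphological_clean(m, 3).any()

    def test_idempotent_on_blob(self, make_disc):
        m = make_disc((60, 60), (30, 30), 20)
        m[30, 30] = False
        once = preprocess.morphological_clean(m, 3)
        twice = preprocess.morphological_clean(once, 3)
        assert np.array_equal(once, twice)

    def test_background_is_single_component(self, pair_scene):
        from skimage import measure

        img, _ = pair_scene
        mask = preprocess.morphological_clean(
            preprocess.binarize_otsu(
                preprocess.gaussian_smooth(preprocess.equalize_histogram(img))
            )
        )
        assert measure.label(~mask, connectivity=1).max() == 1

    def test_even_element_rejected(self):
        with pytest.raises(ValueError):
            preprocess.morphological_clean(np.ones((5, 5), bool), 4)
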