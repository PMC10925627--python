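"""Shape-generation pipeline: noise, smoothing, Otsu, morphology,
components, compactness and bank construction."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import morphology as skmorph

import lesionbench as lb
from lesionbench.errors import DegenerateInputError, GenerationExhaustedError
from lesionbench.lesion_forge import (
    IRREGULAR,
    REGULAR,
    REJECTED,
    apply_irregular_morphology,
    apply_regular_morphology,
    binarize_otsu,
    classify_shape,
    component_from_mask,
    extract_candidates,
    finalize_lesion,
    smooth_gaussian,
)


class TestGenerateNoise:
    def test_deterministic_and_seed_sensitive(self):
        a = lb.generate_noise(0, 256)
        b = lb.generate_noise(0, 256)
        c = lb.generate_noise(1, 256)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_uniform_moments(self):
        # sample mean within 4 standard errors of 1/2 (var of U(0,1) is 1/12)
        img = lb.generate_noise(0, 256)
        se = np.sqrt(1 / 12 / img.size)
        assert abs(img.mean() - 0.5) < 4 * se
        assert img.min() >= 0 and img.max() <= 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            lb.generate_noise(0, 16)


class TestSmoothing:
    def test_constant_preserved(self):
        img = np.full((32, 32), 0.37)
        assert np.allclose(smooth_gaussian(img, 2.0), img)

    def test_impulse_mass_conserved(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        assert abs(smooth_gaussian(img, 2.0).sum() - 1.0) < 1e-6

    def test_checkerboard_variance_reduced(self):
        # independent oracle: dense convolution with an explicit kernel
        yy, xx = np.mgrid[0:40, 0:40]
        img = ((yy + xx) % 2).astype(float)
        out = smooth_gaussian(img, 2.0)
        assert out.var() < img.var()
        r = 8
        k1 = np.exp(-0.5 * (np.arange(-r, r + 1) / 2.0) ** 2)
        kern = np.outer(k1, k1)
        kern /= kern.sum()
        dense = ndi.convolve(img, kern, mode="reflect")
        assert np.allclose(out, dense, atol=1e-4)


class TestOtsu:
    def test_bimodal_split(self):
        img = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)]).reshape(10, 10)
        out = binarize_otsu(img)
        assert out.sum() == 50
        assert set(np.unique(out)) == {0, 1}

    def test_binary_input_reproduced(self):
        rng = np.random.default_rng(3)
        img = (rng.uniform(size=(20, 20)) > 0.5).astype(float)
        assert np.array_equal(binarize_otsu(img), img.astype(np.uint8))

    def test_matches_exhaustive_between_class_variance_search(self):
        # brute-force oracle over all histogram cut points
        rng = np.random.default_rng(7)
        values = rng.choice(np.linspace(0.1, 0.9, 8), size=400)
        img = values.reshape(20, 20)
        out = binarize_otsu(img)
        levels = np.unique(values)
        best_var, best_cut = -1.0, None
        for cut in (levels[:-1] + levels[1:]) / 2:
            lo, hi = values[values <= cut], values[values > cut]
            w0, w1 = lo.size / values.size, hi.size / values.size
            bcv = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if bcv > best_var:
                best_var, best_cut = bcv, cut
        assert np.array_equal(out, (img > best_cut).astype(np.uint8))

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            binarize_otsu(np.full((8, 8), 0.5))


class TestMorphology:
    def test_all_zero_stays_zero(self):
        z = np.zeros((16, 16), np.uint8)
        assert not apply_regular_morphology(z).any()
        assert not apply_irregular_morphology(z).any()

    def test_square_erosion_opening(self):
        img = np.zeros((30, 30), np.uint8)
        img[5:25, 5:25] = 1  # solid 20x20 square
        out = apply_regular_morphology(img)
        expected = np.zeros_like(img)
        expected[6:24, 6:24] = 1  # 18x18 after 3x3 erosion; opening preserves it
        assert np.array_equal(out, expected)

    def test_second_erosion_shrinks_square(self):
        img = np.zeros((30, 30), np.uint8)
        img[6:24, 6:24] = 1
        out = apply_irregular_morphology(img)
        expected = np.zeros_like(img)
        expected[7:23, 7:23] = 1
        assert np.array_equal(out, expected)

    def test_isolated_pixel_and_thin_bar_removed(self):
        img = np.zeros((16, 16), np.uint8)
        img[8, 8] = 1
        assert not apply_regular_morphology(img).any()
        bar = np.zeros((16, 30), np.uint8)
        bar[7:9, 4:26] = 1  # 2-pixel-wide bar
        assert not apply_irregular_morphology(bar).any()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_anti_extensive(self, seed):
        rng = np.random.default_rng(seed)
        img = (rng.uniform(size=(48, 48)) > 0.4).astype(np.uint8)
        reg = apply_regular_morphology(img)
        irr = apply_irregular_morphology(reg)
        assert not (reg & ~img).any()
        assert not (irr & ~reg).any()


class TestComponents:
    def test_two_interior_squares(self):
        img = np.zeros((32, 32), np.uint8)
        img[4:9, 4:9] = 1
        img[20:25, 20:25] = 1
        comps = extract_candidates(img, lb.ForgeConfig(min_area=4))
        assert len(comps) == 2
        assert sorted(c.area for c in comps) == [25, 25]

    def test_border_touching_discarded(self):
        img = np.zeros((32, 32), np.uint8)
        img[0:6, 4:10] = 1
        assert extract_candidates(img, lb.ForgeConfig(min_area=4)) == []

    def test_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(7)
        img = (rng.uniform(size=(64, 64)) > 0.7).astype(np.uint8)
        cfg = lb.ForgeConfig(min_area=1)
        comps = extract_candidates(img, cfg)

        # oracle: labelled flood fill with the same 8-connectivity, then the
        # same border rule
        labels, n = ndi.label(img, structure=np.ones((3, 3)))
        interior = 0
        for lbl in range(1, n + 1):
            ys, xs = np.nonzero(labels == lbl)
            if ys.min() == 0 or xs.min() == 0 or ys.max() == 63 or xs.max() == 63:
                continue
            interior += 1
        assert len(comps) == interior


class TestCompactness:
    def test_ideal_circle_scores_one(self):
        # a component with the continuous circle's area/perimeter relation
        # (p = 2*sqrt(pi*A)) must score exactly 1
        area = 314
        comp = lb.ShapeComponent(
            mask=np.ones((1, 1), bool), area=area, perimeter=2 * np.sqrt(np.pi * area)
        )
        assert lb.compactness(comp) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("radius", [5, 10, 15, 20, 25, 30])
    def test_discretized_disks_score_regular(self, radius):
        disk = np.pad(skmorph.disk(radius), 2)
        comp = component_from_mask(disk)
        assert lb.compactness(comp) > 0.8

    @pytest.mark.parametrize("length", [20, 30, 50])
    def test_thin_lines_score_irregular(self, length):
        line = np.zeros((5, length + 4), bool)
        line[2, 2 : 2 + length] = True
        comp = component_from_mask(line)
        assert lb.compactness(comp) < 0.4

    def test_zero_perimeter_rejected(self):
        comp = lb.ShapeComponent(mask=np.ones((1, 1), bool), area=1, perimeter=0.0)
        with pytest.raises(ValueError):
            lb.compactness(comp)

    @pytest.mark.parametrize(
        "score,expected", [(0.85, REGULAR), (0.35, IRREGULAR), (0.6, REJECTED)]
    )
    def test_classification_thresholds(self, score, expected):
        assert classify_shape(score) == expected


class TestFinalize:
    @pytest.fixture()
    def component(self):
        return component_from_mask(np.pad(skmorph.disk(4), 1))

    def test_peak_equals_w(self, component):
        stamp = finalize_lesion(component, w=0.5)
        assert stamp.patch.max() == pytest.approx(0.5, abs=1e-6)
        assert stamp.shape_class == REGULAR

    def test_margin_taper(self, component):
        stamp = finalize_lesion(component, w=0.5)
        ring = np.ones_like(stamp.patch, dtype=bool)
        ring[1:-1, 1:-1] = False
        assert (stamp.patch[ring] < 0.25).all()

    def test_degenerate_scale_rejected(self, component):
        with pytest.raises(ValueError):
            finalize_lesion(component, w=0.0)

    def test_rejected_band_component_refused(self):
        # a 3x10 solid rectangle scores between 0.4 and 0.8
        comp = component_from_mask(np.pad(np.ones((3, 10), bool), 1))
        assert classify_shape(lb.compactness(comp)) == REJECTED
        with pytest.raises(ValueError):
            finalize_lesion(comp, w=0.5)


class TestBank:
    def test_deterministic(self, forge_config):
        a = lb.build_lesion_bank(5, 5, seed=0, w=0.5, config=forge_config)
        b = lb.build_lesion_bank(5, 5, seed=0, w=0.5, config=forge_config)
        for sa, sb in zip(a.regular + a.irregular, b.regular + b.irregular):
            assert np.array_equal(sa.patch, sb.patch)

    def test_class_bounds_and_rescoring(self, bank):
        for stamp in bank.regular:
            assert stamp.compactness > 0.8
            rescored = lb.compactness(component_from_mask(stamp.component_mask))
            assert rescored == pytest.approx(stamp.compactness, abs=1e-12)
        for stamp in bank.irregular:
            assert stamp.compactness < 0.4

    def test_noise_image_accounting(self, bank):
        assert bank.noise_images_used >= 1

    def test_quota_exhaustion(self, forge_config):
        with pytest.raises(GenerationExhaustedError):
            lb.build_lesion_bank(
                10000, 1, seed=0, w=0.5, config=forge_config, max_noise_images=2
            )

    def test_round_trip(self, bank, tmp_path):
        lb.write_bank(bank, tmp_path)
        loaded = lb.read_bank(tmp_path)
        assert len(loaded.regular) == len(bank.regular)
        for a, b in zip(bank.irregular, loaded.irregular):
            assert a.shape_class == b.shape_class
            assert np.allclose(a.patch, b.patch, atol=1e-4)
            assert np.array_equal(a.component_mask, b.component_mask)
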