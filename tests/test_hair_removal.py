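import numpy as np
import pytest

from dermseg import FixtureSpec, HairConfig, generate_fixture, hair_contour, inpaint, make_hair_mask, rgb_to_gray
from dermseg.hair_removal import InpaintState, _INSIDE, _KNOWN, inpaint_weight, remove_hairs
from dermseg.image_core import InvalidInputError


def stroke_image(h=60, w=60, col=30, width=2, bg=200, fg=20):
    img = np.full((h, w), bg, dtype=np.uint8)
    img[:, col : col + width] = fg
    return img


class TestContour:
    def test_constant_image_silent(self):
        assert hair_contour(np.full((40, 40), 137, dtype=np.uint8)).max() == 0

    def test_thin_dark_stroke_fires(self):
        c = hair_contour(stroke_image())
        assert c[:, 30:32].min() >= 170  # response ~ bg - fg on the stroke
        assert c[:, :10].max() == 0 and c[:, 50:].max() == 0

    def test_wide_structures_silent(self):
        img = np.full((80, 80), 200, dtype=np.uint8)
        img[:, 30:] = 40  # half-plane step, far wider than K
        c = hair_contour(img)
        assert c.max() <= 1

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(InvalidInputError):
            hair_contour(np.zeros((8, 8), dtype=np.uint8))


class TestMask:
    @pytest.mark.parametrize("value,expected", [(0, 0), (9, 0), (10, 255), (11, 255), (255, 255)])
    def test_gray_level_slicing(self, value, expected):
        mask, _ = make_hair_mask(np.array([[value]], dtype=np.uint8))
        assert mask[0, 0] == expected

    def test_zero_contour_reports_no_hairs(self):
        mask, present = make_hair_mask(np.zeros((20, 20), dtype=np.uint8))
        assert not present and mask.max() == 0

    def test_hair_free_image_skips_inpainting(self):
        img = np.full((60, 60, 3), 180, dtype=np.uint8)
        out, present = remove_hairs(img)
        assert not present and np.array_equal(out, img)


class TestWeights:
    @staticmethod
    def state_with_gradient():
        # arrival times increase downward: the normal at (2,2) points down
        T = np.tile(np.arange(5, dtype=float)[:, None], (1, 5))
        flags = np.full((5, 5), _KNOWN, dtype=np.uint8)
        return InpaintState(distance_map=T, flags=flags)

    def test_unit_distance_dst(self):
        st = self.state_with_gradient()
        w = inpaint_weight((2, 2), (2, 1), st)
        # |p-q| = 1 so dst = 1; equal arrival times so lev = 1; dir = 0 (orthogonal to N)
        assert w == pytest.approx(0.0)

    def test_equal_arrival_lev(self):
        st = InpaintState(distance_map=np.zeros((3, 3)), flags=np.full((3, 3), _KNOWN, dtype=np.uint8))
        # zero normal falls back to dir = 1, so w = dst·lev = 1·1
        assert inpaint_weight((1, 1), (1, 0), st) == pytest.approx(1.0)

    def test_aligned_neighbor_full_direction(self):
        st = self.state_with_gradient()
        # q directly above p: p - q is the downward unit vector = N(p)
        assert inpaint_weight((2, 2), (1, 2), st) == pytest.approx(1.0 / (1.0 + 1.0))  # dir=1, dst=1, lev=1/(1+|ΔT|)

    def test_p_equals_q_rejected(self):
        st = self.state_with_gradient()
        with pytest.raises(InvalidInputError):
            inpaint_weight((1, 1), (1, 1), st)


class TestInpaint:
    CFG = HairConfig(dilate_mask=False)

    def test_only_masked_pixels_change(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (40, 40, 3)).astype(np.uint8)
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[10:13, 8:30] = 255
        out = inpaint(img, mask, self.CFG)
        untouched = mask == 0
        assert np.array_equal(out[untouched], img[untouched])
        assert out.dtype == np.uint8

    def test_single_hole_constant_image_exact(self):
        img = np.full((20, 20, 3), 120, dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[10, 10] = 255
        out = inpaint(img, mask, self.CFG)
        assert (out[10, 10] == 120).all()

    def test_single_hole_linear_ramp_exact(self):
        ramp = np.tile(np.arange(40, 200, 4, dtype=np.uint8)[None, :, None], (20, 1, 3))
        mask = np.zeros(ramp.shape[:2], dtype=np.uint8)
        mask[9, 21] = 255
        out = inpaint(ramp, mask, self.CFG)
        assert abs(int(out[9, 21, 0]) - int(ramp[9, 21, 0])) <= 1

    def test_stroke_over_constant_background(self):
        img = np.full((60, 60, 3), 180, dtype=np.uint8)
        img[:, 30:32] = 40
        mask = np.zeros((60, 60), dtype=np.uint8)
        mask[:, 30:32] = 255
        out = inpaint(img, mask, HairConfig())
        assert np.abs(out[:, 30:32].astype(int) - 180).max() <= 2

    def test_fill_order_follows_distance_map(self):
        """First filled pixel must touch the initial boundary; distances are
        non-decreasing along the fill."""
        img = np.full((30, 30, 3), 100, dtype=np.uint8)
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[10:20, 10:20] = 255
        order = []
        import dermseg.hair_removal as hr

        orig = hr.inpaint_pixel

        def tracker(p, image, state, cfg=None):
            order.append((p, float(state.distance_map[p])))
            return orig(p, image, state, cfg)

        hr.inpaint_pixel, saved = tracker, hr.inpaint_pixel
        try:
            inpaint(img, mask, self.CFG)
        finally:
            hr.inpaint_pixel = saved
        (first, _), dists = order[0], [d for _, d in order]
        assert min(abs(first[0] - r) + abs(first[1] - c) for r in (9, 20) for c in (9, 20)) <= 11
        assert first[0] in (10, 19) or first[1] in (10, 19)  # on the region rim
        assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:]))


def test_residual_blackhat_energy_drops_on_hair_fixture():
    fx = generate_fixture(FixtureSpec(seed=1, size=(160, 160), hairs=True))
    before = hair_contour(rgb_to_gray(fx.image)).astype(np.int64).sum()
    out, present = remove_hairs(fx.image)
    assert present
    after = hair_contour(rgb_to_gray(out)).astype(np.int64).sum()
    assert after < before


def test_unmasked_lesion_pixels_survive_hair_removal():
    fx = generate_fixture(FixtureSpec(seed=3, size=(160, 160), hairs=True))
    contour = hair_contour(rgb_to_gray(fx.image))
    mask, present = make_hair_mask(contour)
    assert present
    out = inpaint(fx.image, mask, HairConfig())  # default config dilates by 1 px
    from scipy import ndimage

    inpainted = ndimage.binary_dilation(mask == 255, structure=np.ones((3, 3), dtype=bool))
    assert np.array_equal(out[~inpainted], fx.image[~inpainted])
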