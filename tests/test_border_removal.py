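import numpy as np
import pytest

from dermseg import (
    BorderSearchConfig,
    FixtureSpec,
    InvalidInputError,
    detect_inner_rectangle,
    detect_outer_contour,
    find_inner_corner,
    generate_fixture,
    remove_borders,
    rgb_to_gray,
)
from dermseg.border_removal import embed_mask
from dermseg.image_core import BorderRemovalError

from conftest import frame_with_border


def corner_wedges(h, w, depth, border_val=1, body_val=200):
    """Dark triangular wedges touching all four corners."""
    img = np.full((h, w), body_val, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    for m in (
        yy + xx <= depth,
        yy + (w - 1 - xx) <= depth,
        (h - 1 - yy) + xx <= depth,
        (h - 1 - yy) + (w - 1 - xx) <= depth,
    ):
        img[m] = border_val
    return img


def bfs_components_touching_corners(dark: np.ndarray) -> set:
    """Brute-force 8-connected flood fill; returns pixels of corner-touching components."""
    h, w = dark.shape
    seen = np.zeros_like(dark, dtype=bool)
    keep: set = set()
    for r0, c0 in ((0, 0), (0, w - 1), (h - 1, w - 1), (h - 1, 0)):
        if not dark[r0, c0] or seen[r0, c0]:
            continue
        stack = [(r0, c0)]
        comp = []
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and dark[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        keep.update(comp)
    return keep


def oracle_inner_corner_tl(gray: np.ndarray, threshold: int, extent: int):
    """Exhaustive diagonal scan: first position from `extent` inward whose
    value and two diagonal predecessors are all below the threshold."""
    for i in range(extent, 1, -1):
        if all(gray[i - k, i - k] < threshold for k in range(3)):
            return (i, i)
    return None


class TestOuterContour:
    def test_edge_touching_borders_yield_image_corners(self):
        img = corner_wedges(435, 435, depth=30)
        assert detect_outer_contour(img) == [[0, 0], [0, 434], [434, 434], [434, 0]]

    def test_bright_image_has_no_contour(self):
        assert detect_outer_contour(np.full((50, 50), 200, dtype=np.uint8)) == []

    def test_dark_blob_not_touching_corner_ignored(self):
        img = np.full((60, 60), 200, dtype=np.uint8)
        img[25:35, 25:35] = 0
        assert detect_outer_contour(img) == []

    def test_matches_flood_fill_oracle(self):
        img = corner_wedges(100, 100, depth=18)
        keep = bfs_components_touching_corners(img < 4)
        endpoints = detect_outer_contour(img)
        assert endpoints == [[0, 0], [0, 99], [99, 99], [99, 0]]
        assert all(tuple(p) in keep for p in endpoints)


class TestInnerCorner:
    def test_walk_rejects_then_advances(self):
        """Diagonal (5,5)=144, (4,4)=124, (3,3)=3: the test at (5,5) is false
        because 144 and 124 are not below T=4; the walk advances inward."""
        g = np.full((30, 30), 200, dtype=np.uint8)
        for i, val in ((1, 1), (2, 2), (3, 3), (4, 124), (5, 144)):
            g[i, i] = val
        assert not (g[5, 5] < 4 and g[4, 4] < 4 and g[3, 3] < 4)
        pt = find_inner_corner(g, BorderSearchConfig(estimated_extent=5))
        assert pt.found and (pt.row, pt.col) == (3, 3)

    def test_all_bright_diagonal_not_found(self):
        g = np.full((40, 40), 200, dtype=np.uint8)
        assert not find_inner_corner(g).found

    def test_dark_corner_block(self):
        g = np.full((100, 100), 200, dtype=np.uint8)
        g[:8, :] = 0
        g[:, :8] = 0
        pt = find_inner_corner(g)
        assert (pt.row, pt.col, pt.found) == (7, 7, True)

    @pytest.mark.parametrize("thickness", [4, 8, 12, 16, 20])
    def test_frame_thickness_recovery_matches_oracle(self, thickness):
        g = frame_with_border(120, 120, thickness)
        pt = find_inner_corner(g)
        expected = oracle_inner_corner_tl(g, 4, 20)
        assert expected == (thickness - 1, thickness - 1)
        assert pt.found and (pt.row, pt.col) == expected

    @pytest.mark.parametrize("orientation,expected", [("TL", (7, 7)), ("TR", (7, 112)), ("BL", (112, 7)), ("BR", (112, 112))])
    def test_orientations(self, orientation, expected):
        g = frame_with_border(120, 120, 8)
        pt = find_inner_corner(g, orientation=orientation)
        assert pt.found and (pt.row, pt.col) == expected

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidInputError):
            find_inner_corner(np.zeros((10, 10), dtype=np.uint8))


class TestInnerRectangle:
    def test_early_exit_on_borderless_image(self):
        rects = detect_inner_rectangle(np.full((100, 100), 200, dtype=np.uint8))
        assert not rects.borders_present
        assert rects.searches_run == 1  # only the top-left search ran

    def test_uniform_frame(self):
        g = frame_with_border(300, 300, 12)
        rects = detect_inner_rectangle(g)
        assert rects.borders_present and rects.searches_run == 4
        corners = [(p.row, p.col) for p in (rects.inner_tl, rects.inner_tr, rects.inner_bl, rects.inner_br)]
        assert corners == [(11, 11), (11, 288), (288, 11), (288, 288)]

    def test_partial_borders_default_to_image_edge(self):
        g = np.full((120, 120), 200, dtype=np.uint8)
        g[:8, :30] = 0  # only a top-left border patch
        g[:30, :8] = 0
        rects = detect_inner_rectangle(g)
        assert rects.borders_present
        assert rects.inner_tl.found and not rects.inner_br.found
        img = np.stack([g] * 3, axis=-1)
        crop, offset = remove_borders(img, rects)
        assert offset == (8, 8)
        assert crop.shape[:2] == (112, 112)  # unfound sides are not cropped


class TestRemoveBorders:
    def test_borderless_passthrough(self):
        img = np.full((50, 60, 3), 150, dtype=np.uint8)
        rects = detect_inner_rectangle(rgb_to_gray(img))
        out, offset = remove_borders(img, rects)
        assert offset == (0, 0) and np.array_equal(out, img)

    def test_crop_arithmetic_and_bit_identity(self):
        g = frame_with_border(200, 200, 10)
        rng = np.random.default_rng(3)
        img = np.stack([g] * 3, axis=-1)
        img[g == 200] = rng.integers(100, 200, (int((g == 200).sum()), 3))
        rects = detect_inner_rectangle(rgb_to_gray(img))
        crop, offset = remove_borders(img, rects)
        assert offset == (10, 10) and crop.shape == (180, 180, 3)
        assert np.array_equal(crop, img[10:190, 10:190])

    def test_mask_embedding_zeroes_the_ring(self):
        g = frame_with_border(80, 80, 6)
        img = np.stack([g] * 3, axis=-1)
        rects = detect_inner_rectangle(g)
        crop, offset = remove_borders(img, rects)
        full = np.full(crop.shape[:2], 255, dtype=np.uint8)
        embedded = embed_mask(full, offset, (80, 80))
        assert (embedded[g < 4] == 0).all()
        assert (embedded == 255).sum() == full.size

    def test_degenerate_interior_rejected(self):
        g = np.zeros((30, 30), dtype=np.uint8)  # fully dark: inner corners cross over
        rects = detect_inner_rectangle(g)
        with pytest.raises(BorderRemovalError):
            remove_borders(np.stack([g] * 3, axis=-1), rects)

    def test_idempotence_on_clean_frame(self):
        g = frame_with_border(150, 150, 9)
        img = np.stack([g] * 3, axis=-1)
        crop, _ = remove_borders(img, detect_inner_rectangle(g))
        rects2 = detect_inner_rectangle(rgb_to_gray(crop))
        crop2, offset2 = remove_borders(crop, rects2)
        assert not rects2.borders_present and offset2 == (0, 0)
        assert np.array_equal(crop2, crop)


def test_synthetic_border_fixture_recovery():
    """Thickness-10 synthetic borders are recovered at the (9, 9) inner corner."""
    fx = generate_fixture(FixtureSpec(seed=2, size=(192, 192), borders=True, border_thickness=10))
    rects = detect_inner_rectangle(rgb_to_gray(fx.image))
    assert rects.borders_present
    assert abs(rects.inner_tl.row - 9) <= 1 and abs(rects.inner_tl.col - 9) <= 1
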