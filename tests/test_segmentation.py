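import numpy as np
import pytest
from scipy import ndimage

from rnadist.errors import InputError, SegmentationFailure
from rnadist.segmentation import (
    BinaryMask,
    MaskEdit,
    SegmentationParams,
    auto_edge_threshold,
    cell_mask,
    edit_mask,
    nuclear_mask,
    otsu_threshold,
    rasterize_polygon,
    sobel_gradient,
    unsharp_mask,
    wiener_denoise,
)

KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
KY = KX.T


def sobel_oracle(img):
    """Independent 3x3 correlation with edge-replicated borders."""
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, 1, mode="edge")
    h, w = img.shape
    out = np.zeros((h, w))
    for j in range(h):
        for i in range(w):
            win = padded[j : j + 3, i : i + 3]
            gx = (KX * win).sum()
            gy = (KY * win).sum()
            out[j, i] = np.hypot(gx, gy)
    return out


def otsu_oracle(values):
    """Exhaustive scan over every candidate integer threshold."""
    flat = np.asarray(values).ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in range(int(flat.min()), int(flat.max())):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def disk_image(shape, center, radius, high=200.0, low=10.0):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2
    return np.where(inside, high, low), inside


class TestSobelGradient:
    def test_constant_image_zero_gradient(self):
        assert sobel_gradient(np.full((10, 10), 7.0)).max() == 0.0

    @pytest.mark.parametrize("h", [1.0, 10.0, 255.0])
    def test_step_edge_scales_with_height(self, h):
        img = np.zeros((9, 9))
        img[:, 5:] = h
        grad = sobel_gradient(img)
        assert grad[:, 4:6].min() == pytest.approx(4.0 * h)
        assert grad[:, :3].max() == 0.0

    def test_matches_hand_convolution_oracle(self, rng):
        img = rng.integers(0, 100, size=(5, 5)).astype(float)
        np.testing.assert_allclose(sobel_gradient(img), sobel_oracle(img), rtol=1e-12)

    def test_matches_oracle_larger(self, rng):
        img = rng.integers(0, 4096, size=(64, 64)).astype(float)
        np.testing.assert_allclose(sobel_gradient(img), sobel_oracle(img), rtol=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(InputError):
            sobel_gradient(np.ones((2, 8)))


class TestAutoEdgeThreshold:
    def test_scale_equivariance(self, rng):
        grad = rng.random((20, 20)) + 0.1
        t1 = auto_edge_threshold(grad)
        t3 = auto_edge_threshold(grad * 3.0)
        assert t3 == pytest.approx(3.0 * t1)

    def test_matches_rms_oracle(self, rng):
        grad = rng.random((16, 16))
        total = 0.0
        for row in grad:
            for g in row:
                total += g * g
        expected = (total / grad.size) ** 0.5 * 4.0
        assert auto_edge_threshold(grad) == pytest.approx(expected, rel=1e-12)

    def test_lower_multiplier_detects_more_edges(self, rng):
        img, _ = disk_image((128, 128), (63.5, 63.5), 40)
        img = img + rng.normal(0, 2, img.shape)
        grad = sobel_gradient(img)
        base = auto_edge_threshold(grad)
        edges_loose = grad > base * 0.5
        edges_strict = grad > base * 1.0
        assert np.all(edges_loose | ~edges_strict)  # superset
        assert edges_loose.sum() > edges_strict.sum()

    def test_all_zero_gradient_rejected(self):
        with pytest.raises(InputError):
            auto_edge_threshold(np.zeros((8, 8)))


class TestWienerDenoise:
    def test_constant_unchanged(self):
        img = np.full((12, 12), 42.0)
        np.testing.assert_allclose(wiener_denoise(img), img)

    def test_reduces_noise_variance(self, rng):
        img = 100.0 + rng.normal(0, 10, (64, 64))
        out = wiener_denoise(img)
        assert out.var() < img.var()

    def test_step_edge_position_preserved(self, rng):
        img = np.zeros((32, 64))
        img[:, 32:] = 100.0
        noisy = img + rng.normal(0, 3, img.shape)

        def crossing(im):
            profile = im.mean(axis=0)
            return int(np.argmax(profile > 50.0))

        assert abs(crossing(wiener_denoise(noisy)) - crossing(noisy)) <= 1

    def test_too_small_rejected(self):
        with pytest.raises(InputError):
            wiener_denoise(np.ones((4, 10)))


class TestUnsharpMask:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 9.0)
        np.testing.assert_allclose(unsharp_mask(img), img)

    def test_step_edge_overshoot(self):
        img = np.zeros((16, 32))
        img[:, 16:] = 100.0
        out = unsharp_mask(img)
        assert out.max() > 100.0

    def test_gradient_max_increases_on_faint_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 5.0
        before = sobel_gradient(img).max()
        after = sobel_gradient(unsharp_mask(img)).max()
        assert after > before

    def test_clip_max_respected(self):
        img = np.zeros((16, 32))
        img[:, 16:] = 100.0
        assert unsharp_mask(img, clip_max=100.0).max() == 100.0


class TestOtsu:
    def test_bimodal_two_value_histogram(self, rng):
        values = np.concatenate([np.full(800, 10), np.full(200, 200)])
        rng.shuffle(values)
        t = otsu_threshold(values.reshape(40, 25))
        assert 10 <= t < 200

    def test_matches_exhaustive_oracle_exactly(self, rng):
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        img[20:40, 20:40] = rng.integers(180, 256, size=(20, 20))
        assert otsu_threshold(img) == otsu_oracle(img)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_oracle_agreement_random_bimodal(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [
                rng.integers(0, 80, size=3000),
                rng.integers(120, 250, size=1000),
            ]
        ).astype(np.uint8)
        assert otsu_threshold(img) == otsu_oracle(img)


class TestCellMask:
    @staticmethod
    def _boundary_radii(mask):
        boundary = mask.pixels & ~ndimage.binary_erosion(mask.pixels)
        bys, bxs = np.nonzero(boundary)
        return np.hypot(bxs - 99.5, bys - 99.5)

    def test_disk_recovered_within_2px_before_dilation(self):
        img, _ = disk_image((200, 200), (99.5, 99.5), 50)
        br = self._boundary_radii(
            cell_mask(img, SegmentationParams(dilation_iterations=0))
        )
        assert br.min() >= 48.0 and br.max() <= 52.0

    def test_disk_recovered_default_path(self):
        # the default 1-px square dilation reaches sqrt(2) px diagonally,
        # so the default-path bound is +2 + sqrt(2) on the outside
        img, _ = disk_image((200, 200), (99.5, 99.5), 50)
        br = self._boundary_radii(cell_mask(img, SegmentationParams()))
        assert br.min() >= 48.0 and br.max() <= 52.0 + np.sqrt(2.0)

    def test_largest_component_kept(self):
        img = np.full((256, 256), 10.0)
        big, _ = disk_image((256, 256), (80.0, 80.0), 50, high=200, low=0)
        small, _ = disk_image((256, 256), (200.0, 200.0), 20, high=200, low=0)
        img = np.maximum(img, np.maximum(big, small))
        mask = cell_mask(img)
        assert mask.pixels[80, 80]
        assert not mask.pixels[200, 200]

    def test_constant_image_fails(self):
        with pytest.raises(SegmentationFailure):
            cell_mask(np.full((64, 64), 55.0))

    def test_failure_carries_intermediates(self):
        try:
            cell_mask(np.full((64, 64), 55.0))
        except SegmentationFailure as exc:
            assert "gradient" in exc.intermediates
        else:
            pytest.fail("expected SegmentationFailure")

    def test_single_component_and_hole_free(self, rng):
        img, _ = disk_image((128, 128), (63.5, 63.5), 40)
        img = img + rng.normal(0, 2, img.shape)
        mask = cell_mask(img)
        _, n = ndimage.label(mask.pixels, structure=np.ones((3, 3)))
        assert n == 1
        np.testing.assert_array_equal(
            ndimage.binary_fill_holes(mask.pixels), mask.pixels
        )

    def test_dilation_iterations_grow_straight_edge(self):
        # straight-edge fixture: bright half-plane; compare edge position
        img = np.zeros((64, 64))
        img[:, 24:] = 200.0
        cols = {}
        for k in (1, 3):
            mask = cell_mask(img, SegmentationParams(dilation_iterations=k))
            cols[k] = int(np.nonzero(mask.pixels.any(axis=0))[0].min())
        assert cols[1] - cols[3] == 2  # 2 extra dilations -> 2 px further left


class TestNuclearMask:
    def test_nucleus_recovered_within_2px(self):
        cell_img, cell_true = disk_image((200, 200), (99.5, 99.5), 70)
        nuc_img, nuc_true = disk_image((200, 200), (109.5, 99.5), 25, high=250, low=5)
        cell = cell_mask(cell_img)
        nuc = nuclear_mask(nuc_img, cell)
        boundary = nuc.pixels & ~ndimage.binary_erosion(nuc.pixels)
        bys, bxs = np.nonzero(boundary)
        br = np.hypot(bxs - 109.5, bys - 99.5)
        assert br.min() >= 23.0 and br.max() <= 27.0

    def test_nucleus_outside_cell_removed(self):
        cell_img, _ = disk_image((256, 256), (80.0, 80.0), 60)
        inside, _ = disk_image((256, 256), (80.0, 80.0), 20, high=250, low=5)
        outside, _ = disk_image((256, 256), (200.0, 200.0), 20, high=250, low=0)
        nuc_img = np.maximum(inside, outside)
        cell = cell_mask(cell_img)
        nuc = nuclear_mask(nuc_img, cell)
        assert nuc.pixels[80, 80]
        assert not nuc.pixels[200, 200]
        assert cell.contains(nuc)

    def test_empty_nucleus_fails(self):
        cell_img, _ = disk_image((128, 128), (63.5, 63.5), 40)
        cell = cell_mask(cell_img)
        with pytest.raises(SegmentationFailure):
            # nucleus signal entirely outside the cell
            nuc_img, _ = disk_image((128, 128), (10.0, 10.0), 6, high=250, low=0)
            nuclear_mask(nuc_img, cell)


def square_mask(shape=(64, 64), lo=20, hi=40, kind="cell"):
    px = np.zeros(shape, dtype=bool)
    px[lo:hi, lo:hi] = True
    return BinaryMask(px, kind=kind)


class TestEditMask:
    def test_limit_with_superset_polygon_is_noop(self):
        mask = square_mask()
        poly = [(0, 0), (63, 0), (63, 63), (0, 63)]
        out = edit_mask(mask, MaskEdit("limit", poly))
        np.testing.assert_array_equal(out.pixels, mask.pixels)
        assert out.provenance == "edited"
        assert len(out.edit_log) == 1

    def test_expand_disjoint_adds_area(self):
        mask = square_mask()
        poly = [(50, 50), (60, 50), (60, 60), (50, 60)]
        raster = rasterize_polygon(poly, mask.pixels.shape)
        out = edit_mask(mask, MaskEdit("expand", poly))
        assert out.area_px == mask.area_px + raster.sum()

    def test_draw_triangle_area_matches_shoelace(self):
        verts = [(5.0, 5.0), (55.0, 8.0), (20.0, 50.0)]
        # shoelace oracle
        x = [v[0] for v in verts]
        y = [v[1] for v in verts]
        analytic = 0.5 * abs(
            sum(x[i] * y[(i + 1) % 3] - x[(i + 1) % 3] * y[i] for i in range(3))
        )
        perimeter = sum(
            np.hypot(x[(i + 1) % 3] - x[i], y[(i + 1) % 3] - y[i]) for i in range(3)
        )
        out = edit_mask(square_mask(), MaskEdit("draw", verts))
        assert abs(out.area_px - analytic) <= perimeter

    def test_dilate_grows_one_pixel(self):
        mask = square_mask()
        out = edit_mask(mask, MaskEdit("dilate"))
        assert out.pixels[19, 19] and out.pixels[40, 40]  # diagonal growth
        assert out.area_px == 22 * 22  # 20x20 square grown by 1 px on each side

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (10, 10), (10, 0), (0, 10)]
        with pytest.raises(InputError):
            edit_mask(square_mask(), MaskEdit("draw", bowtie))

    def test_limit_to_empty_fails(self):
        poly = [(50, 50), (60, 50), (60, 60), (50, 60)]
        with pytest.raises(SegmentationFailure):
            edit_mask(square_mask(), MaskEdit("limit", poly))

    def test_edit_log_accumulates(self):
        mask = square_mask()
        out = edit_mask(mask, MaskEdit("dilate"))
        out = edit_mask(out, MaskEdit("dilate"))
        assert len(out.edit_log) == 2
        assert len(mask.edit_log) == 0  # original untouched


class TestParams:
    def test_defaults_match_automatic_path(self):
        p = SegmentationParams()
        assert p.edge_threshold_multiplier == 0.5
        assert p.dilation_iterations == 1
        assert p.wiener_iterations == 0
        assert p.sharpen_iterations == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(InputError):
            SegmentationParams(edge_threshold_multiplier=0.0)
        with pytest.raises(InputError):
            SegmentationParams(dilation_iterations=-1)
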