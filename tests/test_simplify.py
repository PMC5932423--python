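import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from prosthevis.imaging import GrayImage
from prosthevis.simplify import (
    CartoonParams,
    DiffusionParams,
    anisotropic_diffuse,
    cartoonise,
    diffusion_coefficient,
    edge_weight,
    edge_weighted,
    gradient_magnitude,
    quantize_luminance,
    simplify_chain,
    sobel_gradients,
)

unit_images = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(st.integers(4, 12), st.integers(4, 12)),
    elements=st.floats(0.0, 1.0, allow_nan=False),
)


class TestSobel:
    def test_constant_image_zero_response(self):
        g_h, g_v = sobel_gradients(GrayImage(np.full((6, 6), 0.3)))
        np.testing.assert_allclose(g_h, 0.0, atol=1e-14)
        np.testing.assert_allclose(g_v, 0.0, atol=1e-14)

    def test_vertical_step_drives_horizontal_response_only(self):
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        g_h, g_v = sobel_gradients(GrayImage(img))
        assert np.abs(g_h[:, 3:5]).min() > 0
        np.testing.assert_array_equal(g_v, 0)

    def test_hand_convolved_patch(self):
        """Centre response of [[0,0,1]]*3 is 4 under the [-1 0 1; -2 0 2; -1 0 1] kernel."""
        patch = np.array([[0.0, 0.0, 1.0]] * 3)
        g_h, _ = sobel_gradients(GrayImage(patch))
        assert g_h[1, 1] == pytest.approx(4.0)


class TestDiffusionCoefficient:
    @pytest.mark.parametrize("gh,gv,c", [(0.0, 0.0, 1.0), (1.0, 0.0, 0.5), (1.0, 1.0, 1 / 3)])
    def test_closed_form(self, gh, gv, c):
        out = diffusion_coefficient(np.full((2, 2), gh), np.full((2, 2), gv))
        assert out[0, 0] == pytest.approx(c)

    def test_monotone_decreasing_in_gradient(self):
        g = np.linspace(0, 5, 50).reshape(1, -1)
        c = diffusion_coefficient(g, np.zeros_like(g)).ravel()
        assert np.all(np.diff(c) < 0)


class TestAnisotropicDiffuse:
    def test_constant_image_is_fixed_point(self):
        img = GrayImage(np.full((10, 10), 0.7))
        out = anisotropic_diffuse(img, DiffusionParams(dt=0.25, n_iter=30))
        np.testing.assert_allclose(out.pixels, 0.7)

    def test_checkerboard_variance_decays_monotonically(self):
        img = GrayImage(np.indices((16, 16)).sum(axis=0) % 2 * 0.6 + 0.2)
        variances = [img.pixels.var()]
        current = img
        for _ in range(10):
            current = anisotropic_diffuse(current, DiffusionParams(n_iter=1))
            variances.append(current.pixels.var())
        assert np.all(np.diff(variances) < 0)

    def test_maximum_principle(self, rng):
        img = GrayImage(rng.random((20, 20)) * 0.5 + 0.25)
        out = anisotropic_diffuse(img, DiffusionParams(dt=0.25, n_iter=20))
        assert out.pixels.min() >= img.pixels.min() - 1e-12
        assert out.pixels.max() <= img.pixels.max() + 1e-12

    def test_step_edge_location_preserved(self):
        """The half-height crossing of a strong edge stays put under diffusion."""
        img = np.full((12, 40), 0.1)
        img[:, 20:] = 0.9
        out = anisotropic_diffuse(GrayImage(img), DiffusionParams(n_iter=20))

        def crossing(row):
            return int(np.argmax(row >= 0.5))

        assert crossing(out.pixels[6]) == crossing(img[6])

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            DiffusionParams(dt=0.3)


class TestGradientMagnitude:
    def test_matches_per_pixel_sobel_oracle(self, rng):
        img = GrayImage(rng.random((12, 12)))
        grad = gradient_magnitude(img)
        g_h, g_v = sobel_gradients(img)
        np.testing.assert_allclose(grad.values, np.sqrt(g_h**2 + g_v**2))
        assert grad.normalized.max() == pytest.approx(1.0)

    def test_flat_image_warns(self):
        with pytest.warns(UserWarning, match="flat image"):
            grad = gradient_magnitude(GrayImage(np.full((6, 6), 0.4)))
        assert np.all(grad.normalized == 0)


class TestQuantize:
    def test_bin_center_is_fixed_point(self):
        cp = CartoonParams(n_bins=4)
        img = GrayImage(np.full((4, 4), 0.375))  # centre of bin 1
        out = quantize_luminance(img, cp)
        np.testing.assert_allclose(out.pixels, 0.375)

    @given(unit_images)
    @settings(max_examples=25, deadline=None)
    def test_quantization_bound(self, px):
        """Every pixel stays within half a bin of its nearest bin centre."""
        cp = CartoonParams(n_bins=8)
        out = quantize_luminance(GrayImage(px), cp)
        centers = (np.arange(cp.n_bins) + 0.5) * cp.bin_size
        dist = np.abs(out.pixels[..., None] - centers).min(axis=-1)
        assert np.all(dist <= cp.bin_size / 2 + 1e-12)

    def test_sharp_quantizer_builds_staircase(self):
        """At large phi the tanh saturates, collapsing a smooth ramp onto the
        bin-boundary levels k*dq (n_bins+1 plateau values)."""
        ramp = GrayImage(np.tile(np.linspace(0, 1, 256), (4, 1)))
        cp = CartoonParams(n_bins=5, phi_q=100.0)
        out = quantize_luminance(ramp, cp)
        levels = np.arange(cp.n_bins + 1) * cp.bin_size
        near_level = np.abs(out.pixels[..., None] - levels).min(axis=-1) < 0.01
        assert near_level.mean() > 0.8
        # the soft quantizer at moderate phi does NOT collapse that hard
        soft = quantize_luminance(ramp, CartoonParams(n_bins=5, phi_q=5.0))
        soft_near = np.abs(soft.pixels[..., None] - levels).min(axis=-1) < 0.01
        assert soft_near.mean() < near_level.mean()


class TestCartoonAndEdgeWeight:
    def test_cartoon_passthrough_and_blackout(self):
        q = GrayImage(np.full((4, 4), 0.6))
        with pytest.warns(UserWarning):
            grad_zero = gradient_magnitude(GrayImage(np.full((4, 4), 0.5)))
        np.testing.assert_allclose(cartoonise(q, grad_zero).pixels, 0.6)
        # a saturated gradient paints a black contour
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        grad = gradient_magnitude(GrayImage(img))
        out = cartoonise(quantize_luminance(GrayImage(img)), grad)
        assert out.pixels[3, np.argmax(grad.normalized[3])] == pytest.approx(0.0, abs=1e-9)

    def test_disk_gets_dark_boundary_ring(self, disk_scene):
        stages = simplify_chain(disk_scene.visible)
        from scipy.ndimage import binary_dilation, binary_erosion

        mask = disk_scene.masks[0][1]
        ring = binary_dilation(mask, iterations=1) & ~binary_erosion(mask, iterations=2)
        interior = binary_erosion(mask, iterations=4)
        cartoon = stages["cartoon"].pixels
        assert cartoon[ring].mean() < 0.5 * cartoon[interior].mean()

    @pytest.mark.parametrize("floor", [0.0, 0.5, 1.0])
    def test_edge_weight_floor(self, floor, rng):
        grad = gradient_magnitude(GrayImage(rng.random((8, 8))))
        w = edge_weight(grad, floor)
        assert w.values.min() >= floor
        np.testing.assert_allclose(w.values, np.maximum(grad.normalized, floor))

    def test_edge_weight_invalid_floor(self, rng):
        grad = gradient_magnitude(GrayImage(rng.random((8, 8))))
        with pytest.raises(ValueError):
            edge_weight(grad, 1.5)

    def test_edge_weighted_identity_and_dimming(self, rng):
        img = GrayImage(rng.random((8, 8)))
        grad = gradient_magnitude(img)
        ones = edge_weight(grad, 1.0)
        np.testing.assert_allclose(edge_weighted(ones, img).pixels, img.pixels)

    def test_edge_weighting_raises_boundary_contrast(self, disk_scene):
        """The edge band stands out more against background after weighting."""
        from scipy.ndimage import binary_dilation

        stages = simplify_chain(disk_scene.visible)
        mask = disk_scene.masks[0][1]
        band = binary_dilation(mask, iterations=1) & ~mask
        far = ~binary_dilation(mask, iterations=8)

        def contrast(px):
            return px[band].mean() / (px[far].mean() + 1e-9)

        assert contrast(stages["edge_weighted"].pixels) > contrast(stages["cartoon"].pixels)


@given(unit_images)
@settings(max_examples=10, deadline=None)
def test_full_chain_outputs_stay_in_unit_range(px):
    stages = simplify_chain(GrayImage(px), DiffusionParams(n_iter=3))
    for key in ("diffused", "quantized", "cartoon", "edge_weighted"):
        out = stages[key].pixels
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_full_chain_deterministic(person_scene):
    a = simplify_chain(person_scene.visible)
    b = simplify_chain(person_scene.visible)
    np.testing.assert_array_equal(a["edge_weighted"].pixels, b["edge_weighted"].pixels)
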