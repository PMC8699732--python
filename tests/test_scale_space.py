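"""Scale-space kernels and differential invariants against analytic oracles.

Polynomial test images have known derivatives everywhere, so every filter
response can be checked exactly at interior pixels (reflect padding only
perturbs a border strip of one kernel radius).
"""

import math

import numpy as np
import pytest

from geoseg import scale_space as ss


class TestKernels:
    def test_smoothing_kernel_center_and_normalization(self):
        k = ss.make_kernel(ss.GaussianKernelSpec(sigma=1.0))
        c = k.shape[0] // 2
        # 2-D Gaussian at r=0 is 1/(2*pi*s) with s = sigma^2 = 1
        assert k[c, c] == pytest.approx(1.0 / (2 * math.pi), abs=1e-3)
        assert k.sum() == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("sigma", [0.8, 1.5, 3.0])
    def test_smoothing_kernel_even_symmetry(self, sigma):
        k = ss.make_kernel(ss.GaussianKernelSpec(sigma=sigma))
        assert np.allclose(k, k[::-1, :]) and np.allclose(k, k[:, ::-1])

    def test_first_derivative_kernel_antisymmetric_unit_ramp_response(self, ramp_x, interior):
        k = ss.make_kernel(ss.GaussianKernelSpec(sigma=1.5, dx=1, dy=0))
        assert np.allclose(k, -k[:, ::-1], atol=1e-15)
        assert abs(k.sum()) < 1e-14
        resp = ss.gaussian_derivative(ramp_x, 1.5, 1, 0)
        assert np.allclose(resp[interior], 1.0, atol=1e-10)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            ss.GaussianKernelSpec(sigma=-1.0)
        with pytest.raises(ValueError, match="radius"):
            ss.GaussianKernelSpec(sigma=3.0, radius=2)
        with pytest.raises(ValueError, match="dx"):
            ss.GaussianKernelSpec(sigma=1.0, dx=4, dy=3)

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_derivative_kernels_annihilate_lower_degree_polynomials(self, order, coords64, interior):
        x, _ = coords64
        resp = ss.gaussian_derivative(x ** (order - 1), 2.0, order, 0)
        scale = max(np.abs(x ** (order - 1)).max(), 1.0)
        assert np.abs(resp[interior]).max() / scale < 1e-9

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_derivative_kernels_differentiate_their_monomial(self, order, coords64, interior):
        x, _ = coords64
        resp = ss.gaussian_derivative(x**order / math.factorial(order), 2.0, order, 0)
        assert np.allclose(resp[interior], 1.0, atol=1e-8)


class TestGradient:
    def test_uniform_ramp(self, ramp_x, interior):
        g = ss.gradient_features(ramp_x, 2.0)
        assert np.allclose(g["amplitude"][interior], 1.0, atol=1e-10)
        assert np.allclose(g["cos"][interior], 1.0, atol=1e-10)
        assert np.allclose(g["sin"][interior], 0.0, atol=1e-10)

    def test_constant_image_amplitude_zero_orientation_convention(self):
        g = ss.gradient_features(np.full((32, 32), 7.0), 2.0)
        assert np.allclose(g["amplitude"], 0.0, atol=1e-12)
        assert np.all(g["sin"] == 0.0) and np.all(g["cos"] == 0.0)

    def test_oblique_ramp_amplitude(self, coords64, interior):
        x, y = coords64
        g = ss.gradient_features(2 * x + y, 2.0)
        assert np.allclose(g["amplitude"][interior], math.sqrt(5), atol=1e-9)

    def test_orientation_unit_circle_where_nondegenerate(self, rng):
        img = ss.gaussian_smooth(rng.normal(size=(48, 48)), 1.0)
        g = ss.gradient_features(img, 2.0)
        live = g["amplitude"] > 1e-6
        norm = g["sin"][live] ** 2 + g["cos"][live] ** 2
        assert np.allclose(norm, 1.0, atol=1e-12)


class TestSecondOrder:
    def test_laplacian_constant_and_ramp_vanish(self, ramp_x, interior):
        assert np.abs(ss.laplacian_features(np.full((32, 32), 3.0), 2.0)["log"]).max() < 1e-10
        assert np.abs(ss.laplacian_features(ramp_x, 2.0)["log"][interior]).max() < 1e-9

    def test_laplacian_of_paraboloid(self, coords64, interior):
        x, y = coords64
        lap = ss.laplacian_features(x**2 + y**2, 2.0)["log"]
        assert np.allclose(lap[interior], 4.0, atol=1e-8)

    def test_hessian_eigen_identities(self, rng):
        img = rng.normal(size=(48, 48))
        h = ss.hessian_features(img, 2.0)
        lap = ss.laplacian_features(img, 2.0)["log"]
        span = max(np.abs(lap).max(), 1.0)
        assert np.abs(h["lambda1"] + h["lambda2"] - lap).max() < 1e-8 * span
        assert np.abs(h["lambda1"] * h["lambda2"] - h["det"]).max() < 1e-8 * max(
            np.abs(h["det"]).max(), 1.0
        )
        assert np.all(h["lambda1"] >= h["lambda2"] - 1e-14)

    def test_hessian_of_cylindrical_parabola(self, coords64, interior):
        x, _ = coords64
        h = ss.hessian_features(x**2, 2.0)
        assert np.allclose(h["lambda1"][interior], 2.0, atol=1e-8)
        assert np.allclose(h["lambda2"][interior], 0.0, atol=1e-8)
        assert np.allclose(h["det"][interior], 0.0, atol=1e-7)

    def test_dark_blob_has_positive_eigenvalues(self, coords64):
        x, y = coords64
        img = -np.exp(-((x - 32) ** 2 + (y - 32) ** 2) / 50.0)
        h = ss.hessian_features(img, 2.0)
        assert h["lambda2"][32, 32] > 0 and h["lambda1"][32, 32] > 0

    def test_saddle(self, coords64, interior):
        x, y = coords64
        h = ss.hessian_features((x - 32) * (y - 32), 2.0)
        assert np.all(h["lambda1"][interior] > 0.5)
        assert np.all(h["lambda2"][interior] < -0.5)
        assert np.all(h["det"][interior] < 0)


class TestALoG:
    def test_ridge_curvature_all_normal(self, coords64, interior):
        x, _ = coords64
        a = ss.alog_features((x - 32) ** 2, 2.0)
        ok = np.abs(x[interior] - 32) > 3  # away from the degenerate crest line
        assert np.allclose(a["perp"][interior][ok], 2.0, atol=1e-6)
        assert np.allclose(a["par"][interior][ok], 0.0, atol=1e-6)

    def test_decomposition_identity(self, rng):
        img = rng.normal(size=(48, 48))
        a = ss.alog_features(img, 2.0)
        lap = ss.laplacian_features(img, 2.0)["log"]
        assert np.abs(a["perp"] + a["par"] - lap).max() < 1e-10 * max(np.abs(lap).max(), 1.0)

    def test_radial_blob_isophote_component_negative(self, coords64):
        x, y = coords64
        r2 = (x - 32) ** 2 + (y - 32) ** 2
        img = np.exp(-r2 / 128.0)
        a = ss.alog_features(img, 2.0)
        annulus = (r2 > 36) & (r2 < 144)
        # brute-force gauge formula on the smoothed analytic image
        gx = ss.gaussian_derivative(img, 2.0, 1, 0)
        gy = ss.gaussian_derivative(img, 2.0, 0, 1)
        gxx = ss.gaussian_derivative(img, 2.0, 2, 0)
        gyy = ss.gaussian_derivative(img, 2.0, 0, 2)
        gxy = ss.gaussian_derivative(img, 2.0, 1, 1)
        brute = (gy**2 * gxx - 2 * gx * gy * gxy + gx**2 * gyy) / (gx**2 + gy**2)
        assert np.all(a["par"][annulus] < 0)
        assert np.allclose(a["par"][annulus], brute[annulus], atol=1e-12)


class TestStructureTensor:
    def test_aligned_field_coherence_one(self, ramp_x, interior):
        st = ss.structure_tensor_features(ramp_x, 2.0, 2.0)
        assert np.allclose(st["coherence"][interior], 1.0, atol=1e-6)

    def test_isotropic_noise_low_coherence(self, rng):
        img = rng.normal(size=(128, 128))
        st = ss.structure_tensor_features(img, 1.0, 8.0)
        inner = st["coherence"][40:-40, 40:-40]
        assert inner.mean() < 0.25

    def test_coherence_formula(self):
        l1, l2 = 3.0, 1.0
        assert ((l1 - l2) / (l1 + l2)) ** 2 == pytest.approx(0.25)

    def test_eigenvalue_order_and_positivity(self, rng):
        img = rng.normal(size=(48, 48))
        st = ss.structure_tensor_features(img, 1.5, 3.0)
        assert np.all(st["lambda1"] >= st["lambda2"])
        assert st["lambda2"].min() >= -1e-12
        assert st["coherence"].min() >= 0 and st["coherence"].max() <= 1

    def test_sigma_validation(self, ramp_x):
        with pytest.raises(ValueError):
            ss.structure_tensor_features(ramp_x, -1.0, 2.0)


class TestCurvatures:
    def test_line_curvature_of_ramp_is_zero(self, ramp_x, interior):
        c = ss.curvature2d_features(ramp_x, 2.0)
        assert np.abs(c["line_curvature"][interior]).max() < 1e-9

    def test_line_curvature_of_circular_isophotes(self, coords64):
        x, y = coords64
        r = np.hypot(x - 32, y - 32)
        c = ss.curvature2d_features((x - 32) ** 2 + (y - 32) ** 2, 2.0)
        ring = (r > 8) & (r < 14) & (x > 18) & (x < 46) & (y > 18) & (y < 46)
        assert np.allclose(np.abs(c["line_curvature"][ring]), 1.0 / r[ring], rtol=0.05)

    def test_det_plane_shared_with_hessian(self, rng):
        img = rng.normal(size=(32, 32))
        c = ss.curvature2d_features(img, 2.0)
        h = ss.hessian_features(img, 2.0)
        assert np.array_equal(c["det"], h["det"])

    def test_surface_curvatures_vanish_on_planes(self, coords64, interior):
        x, _ = coords64
        for img in (np.full((64, 64), 2.0), 3.0 * x):
            c = ss.curvature3d_features(img, 2.0)
            assert np.abs(c["mean_curvature"][interior]).max() < 1e-8
            assert np.abs(c["gaussian_curvature"][interior]).max() < 1e-8

    def test_hemisphere_curvatures(self):
        R = 40.0
        y, x = np.mgrid[0:33, 0:33].astype(np.float64) - 16
        img = np.sqrt(R**2 - x**2 - y**2)
        c = ss.curvature3d_features(img, 1.0)
        center = (slice(14, 19), slice(14, 19))
        assert np.allclose(c["gaussian_curvature"][center], 1.0 / R**2, rtol=0.05)
        assert np.allclose(np.abs(c["mean_curvature"][center]), 1.0 / R, rtol=0.05)


class TestPowerLaplacian:
    def test_first_power_is_log(self, rng):
        img = rng.normal(size=(32, 32))
        assert np.array_equal(
            ss.power_laplacian(img, 2.0, 1)["log1"], ss.laplacian_features(img, 2.0)["log"]
        )

    def test_bilaplacian_annihilates_cubics(self, coords64, interior):
        x, y = coords64
        resp = ss.power_laplacian(x**3 + y**3 - x * y, 2.0, 2)["log2"]
        assert np.abs(resp[interior]).max() < 1e-6

    def test_bilaplacian_of_quartic(self, coords64):
        x, _ = coords64
        resp = ss.power_laplacian(x**4, 2.0, 2)["log2"]
        inner = (slice(26, 38), slice(26, 38))
        assert np.allclose(resp[inner], 24.0, atol=1e-6)

    def test_order_bounds(self, ramp_x):
        with pytest.raises(ValueError):
            ss.power_laplacian(ramp_x, 2.0, 5)


class TestJet:
    def test_plane_count_and_consistency(self, ramp_x, rng):
        jet = ss.gaussian_jet(ramp_x, 2.0, 2)
        assert len(jet) == 6
        img = rng.normal(size=(48, 48))
        jet = ss.gaussian_jet(img, 2.0, 2)
        lap = ss.laplacian_features(img, 2.0)["log"]
        assert np.allclose(jet["d20"] + jet["d02"], lap, atol=1e-12)
        grad = ss.gradient_features(img, 2.0)
        assert np.array_equal(jet["d10"], grad["gx"])

    def test_first_partial_of_ramp(self, ramp_x, interior):
        jet = ss.gaussian_jet(ramp_x, 2.0, 1)
        assert np.allclose(jet["d10"][interior], 1.0, atol=1e-10)


class TestFeatureStack:
    def test_plane_counts(self, ramp_x):
        spec = ss.ScaleSpec(sigmas=(2.0, 4.0, 8.0))
        assert len(ss.build_feature_stack(ramp_x, spec, ("LoG",)).planes) == 3
        assert len(ss.build_feature_stack(ramp_x, spec, ("ALoG",)).planes) == 15

    def test_unknown_filter_lists_registry(self, ramp_x):
        with pytest.raises(ValueError, match="ALoG"):
            ss.build_feature_stack(ramp_x, filter_names=("Bogus",))

    def test_determinism_and_ordering(self, rng):
        img = rng.normal(size=(40, 40))
        spec = ss.ScaleSpec(sigmas=(2.0, 4.0))
        a = ss.build_feature_stack(img, spec, ("LoG", "Gradient"))
        b = ss.build_feature_stack(img, spec, ("Gradient", "LoG"))
        assert a.names == b.names  # registry order, not request order
        assert a.names[0].startswith("Gradient.amplitude")
        for name in a.names:
            assert np.array_equal(a.planes[name], b.planes[name])

    def test_scale_spec_validation(self):
        with pytest.raises(ValueError):
            ss.ScaleSpec(sigmas=(4.0, 2.0))
        with pytest.raises(ValueError):
            ss.ScaleSpec(sigmas=())


class TestScaleSpaceProperties:
    def test_semigroup_composition(self, rng):
        img = rng.normal(size=(96, 96))
        s1 = s2 = 4.0  # scales (sigma^2); compose to sigma = sqrt(8)
        r = math.ceil(4 * 2.0)
        a = ss.gaussian_smooth(ss.gaussian_smooth(img, 2.0, radius=r), 2.0, radius=r)
        b = ss.gaussian_smooth(img, math.sqrt(s1 + s2), radius=math.ceil(4 * math.sqrt(8)))
        m = 2 * math.ceil(4 * math.sqrt(8))
        rel = np.abs(a - b)[m:-m, m:-m].max() / np.abs(b).max()
        assert rel < 1e-3

    def test_no_new_extrema(self, rng):
        img = rng.uniform(0, 255, size=(64, 64))
        sm = ss.gaussian_smooth(img, 3.0)
        inner = sm[10:-10, 10:-10]
        assert inner.max() <= img.max() + 1e-9
        assert inner.min() >= img.min() - 1e-9

    @pytest.mark.parametrize("extract", [
        lambda i: ss.gradient_features(i, 2.0)["amplitude"],
        lambda i: ss.laplacian_features(i, 2.0)["log"],
        lambda i: ss.hessian_features(i, 2.0)["det"],
        lambda i: ss.hessian_features(i, 2.0)["lambda1"],
        lambda i: ss.structure_tensor_features(i, 2.0, 2.0)["coherence"],
        lambda i: ss.curvature2d_features(i, 2.0)["line_curvature"],
        lambda i: ss.curvature3d_features(i, 2.0)["mean_curvature"],
    ])
    def test_rotation_equivariance_of_invariants(self, rng, extract):
        img = rng.normal(size=(48, 48))
        rotated_then_filtered = extract(np.rot90(img))
        filtered_then_rotated = np.rot90(extract(img))
        inner = (slice(8, -8), slice(8, -8))
        span = max(np.abs(filtered_then_rotated).max(), 1e-12)
        assert np.abs(
            (rotated_then_filtered - filtered_then_rotated)[inner]
        ).max() / span < 1e-10
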