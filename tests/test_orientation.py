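import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radialign import (
    Image2D,
    WeightWindow,
    compute_gradients,
    dominant_direction_bruteforce,
    orientation_coherency,
    orientation_map,
    structure_tensor,
)
from radialign.image import axial_difference_deg, wrap_axial_deg
from radialign.orientation import StructureTensor, directional_energy
from radialign.synthetic import FiberFieldSpec, make_fiber_field, make_grating

from conftest import tensor_of


def brute_force_tensor(grad, window):
    """Independent double-loop weighted-summation oracle for J."""
    w, (r0, r1, c0, c1) = window.weights(grad.shape)
    jxx = jxy = jyy = 0.0
    for i in range(r1 - r0):
        for j in range(c1 - c0):
            fx = grad.fx[r0 + i, c0 + j]
            fy = grad.fy[r0 + i, c0 + j]
            jxx += w[i, j] * fx * fx
            jxy += w[i, j] * fx * fy
            jyy += w[i, j] * fy * fy
    return jxx, jxy, jyy


class TestComputeGradients:
    def test_constant_image_zero_gradient(self):
        g = compute_gradients(Image2D(np.full((32, 32), 3.7)))
        assert np.allclose(g.fx, 0.0) and np.allclose(g.fy, 0.0)

    def test_x_ramp(self):
        y, x = np.mgrid[0:32, 0:32].astype(float)
        g = compute_gradients(Image2D(x), sigma=1.5)
        interior = (slice(8, -8), slice(8, -8))
        # truncated Gaussian kernel recovers a unit slope to ~2e-4
        assert np.allclose(g.fx[interior], 1.0, atol=1e-3)
        assert np.allclose(g.fy[interior], 0.0, atol=1e-6)

    def test_rotated_ramp_45deg(self):
        y, x = np.mgrid[0:48, 0:48].astype(float)
        ramp = (x + y) / np.sqrt(2.0)
        g = compute_gradients(Image2D(ramp), sigma=1.5)
        interior = (slice(10, -10), slice(10, -10))
        # finite-difference check at interior pixels
        fd_x = np.gradient(ramp, axis=1)[interior]
        fd_y = np.gradient(ramp, axis=0)[interior]
        assert np.allclose(g.fx[interior], fd_x, atol=1e-3)
        assert np.allclose(g.fy[interior], fd_y, atol=1e-3)
        assert np.allclose(g.fx[interior], 1.0 / np.sqrt(2.0), atol=1e-3)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="kernel support"):
            compute_gradients(Image2D(np.zeros((4, 4))), sigma=2.0)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            compute_gradients(Image2D(np.zeros((16, 16))), sigma=0.0)


class TestStructureTensor:
    def test_constant_image_zero_tensor(self):
        J = tensor_of(Image2D(np.ones((32, 32))), WeightWindow((15.5, 15.5), 32))
        assert J.jxx == 0.0 and J.jxy == 0.0 and J.jyy == 0.0

    def test_horizontal_grating_jyy_dominates(self):
        img = make_grating(FiberFieldSpec(stripe_angle_deg=0.0, wavelength_px=16.0))
        J = tensor_of(img, WeightWindow((127.5, 127.5), 256))
        assert J.jyy > 100.0 * J.jxx
        assert abs(J.jxy) < 1e-6 * J.jyy

    @pytest.mark.parametrize("profile", ["box", "gaussian"])
    def test_matches_double_loop_oracle(self, profile):
        rng = np.random.default_rng(17)
        img = Image2D(rng.random((40, 40)))
        grad = compute_gradients(img)
        win = WeightWindow(center=(20.0, 18.0), size_L=21, profile=profile)
        J = structure_tensor(grad, win)
        jxx, jxy, jyy = brute_force_tensor(grad, win)
        assert J.jxx == pytest.approx(jxx, rel=1e-10)
        assert J.jxy == pytest.approx(jxy, rel=1e-10)
        assert J.jyy == pytest.approx(jyy, rel=1e-10)

    def test_window_outside_image_raises(self):
        grad = compute_gradients(Image2D(np.random.default_rng(0).random((32, 32))))
        with pytest.raises(ValueError, match="does not intersect"):
            structure_tensor(grad, WeightWindow(center=(500.0, 500.0), size_L=8))

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        img = Image2D(rng.random((48, 48)))
        J = tensor_of(img, WeightWindow((23.5, 23.5), 48))
        assert J.jxx >= 0 and J.jyy >= 0
        assert J.jxx * J.jyy - J.jxy**2 >= -1e-10 * (J.jxx + J.jyy) ** 2


class TestOrientationCoherency:
    def test_isotropic_tensor_invalid(self):
        res = orientation_coherency(StructureTensor(jxx=2.0, jxy=0.0, jyy=2.0))
        assert not res.valid
        assert res.coherency == 0.0
        assert np.isnan(res.theta_deg)

    def test_zero_tensor_invalid(self):
        res = orientation_coherency(StructureTensor(0.0, 0.0, 0.0))
        assert not res.valid and res.coherency == 0.0

    def test_grating_30deg(self, grating30, whole_window):
        res = orientation_coherency(tensor_of(grating30, whole_window))
        assert axial_difference_deg(res.theta_deg, 30.0) < 0.5
        assert res.coherency >= 0.99
        # fiber axis is the gradient axis rotated by 90
        assert axial_difference_deg(res.gradient_axis_deg, res.theta_deg) == pytest.approx(90.0)

    def test_trace_conservation(self, grating30, whole_window):
        J = tensor_of(grating30, whole_window)
        res = orientation_coherency(J)
        assert res.lambda_max + res.lambda_min == pytest.approx(
            J.jxx + J.jyy, rel=1e-10
        )

    def test_intensity_scaling_invariance(self, grating30, whole_window):
        J1 = tensor_of(grating30, whole_window)
        scaled = Image2D(grating30.values * 3.5)
        J2 = tensor_of(scaled, whole_window)
        r1, r2 = orientation_coherency(J1), orientation_coherency(J2)
        assert r2.energy == pytest.approx(3.5**2 * r1.energy, rel=1e-10)
        assert r2.theta_deg == pytest.approx(r1.theta_deg, abs=1e-9)
        assert r2.coherency == pytest.approx(r1.coherency, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        jxx=st.floats(0.0, 1e6),
        jyy=st.floats(0.0, 1e6),
        rho=st.floats(-1.0, 1.0),
    )
    def test_coherency_bounds_property(self, jxx, jyy, rho):
        # |jxy| <= sqrt(jxx*jyy) keeps the tensor PSD
        jxy = rho * np.sqrt(jxx * jyy)
        res = orientation_coherency(StructureTensor(jxx, jxy, jyy))
        assert 0.0 <= res.coherency <= 1.0
        assert res.lambda_max >= res.lambda_min >= -1e-9 * max(jxx + jyy, 1.0)

    def test_coherency_one_iff_rank_one(self):
        res = orientation_coherency(StructureTensor(jxx=4.0, jxy=0.0, jyy=0.0))
        assert res.valid
        assert res.coherency == pytest.approx(1.0)


class TestBruteForceOracle:
    def test_horizontal_grating_gradient_axis_vertical(self):
        img = make_grating(FiberFieldSpec(stripe_angle_deg=0.0, wavelength_px=16.0))
        sweep = dominant_direction_bruteforce(
            img, WeightWindow((127.5, 127.5), 256), angle_step_deg=1.0
        )
        assert axial_difference_deg(sweep.argmax_axis_deg, 90.0) <= 1.0

    def test_rayleigh_identity(self, grating30, whole_window):
        res = orientation_coherency(tensor_of(grating30, whole_window))
        e = directional_energy(grating30, whole_window, res.gradient_axis_deg)
        assert e == pytest.approx(res.lambda_max, rel=1e-8)

    def test_argmax_equals_eigen_axis_on_seeded_fields(self):
        win = WeightWindow(center=(63.5, 63.5), size_L=128)
        step = 1.0
        for seed in range(5):
            spec = FiberFieldSpec(
                height=128, width=128, n_fibers=60,
                orientation_mu_deg=float(seed * 31 % 90),
                orientation_kappa=20.0, seed=seed,
            )
            img = make_fiber_field(spec).image
            res = orientation_coherency(tensor_of(img, win))
            sweep = dominant_direction_bruteforce(img, win, angle_step_deg=step)
            assert axial_difference_deg(
                sweep.argmax_axis_deg, res.gradient_axis_deg
            ) <= step


class TestOrientationMap:
    def test_uniform_grating_consistent_theta(self, grating30):
        m = orientation_map(grating30, window_size_L=32, stride=32)
        thetas = m.theta_deg[m.valid]
        assert m.n_valid > 10
        assert np.all(axial_difference_deg(thetas, 30.0) < 1.0)

    def test_blank_image_all_invalid(self):
        m = orientation_map(Image2D(np.zeros((64, 64))), window_size_L=16)
        assert m.n_valid == 0

    def test_stride_larger_than_image_raises(self):
        img = Image2D(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="stride"):
            orientation_map(img, window_size_L=16, stride=100)

    def test_window_smaller_than_4sigma_raises(self):
        img = Image2D(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="4\\*sigma"):
            orientation_map(img, window_size_L=4, sigma=2.0)

    def test_rotation_equivariance_90deg(self, grating30):
        m0 = orientation_map(grating30, window_size_L=32, stride=32)
        rot = Image2D(np.rot90(grating30.values))
        m90 = orientation_map(rot, window_size_L=32, stride=32)
        t0 = m0.theta_deg[m0.valid]
        t90 = m90.theta_deg[m90.valid]
        # interior tiles: compare medians (tile sets correspond up to layout)
        exp = wrap_axial_deg(np.median(t0) + 90.0)
        assert axial_difference_deg(np.median(t90), exp) < 2.0
        assert np.median(m90.coherency[m90.valid]) == pytest.approx(
            np.median(m0.coherency[m0.valid]), abs=1e-6
        )
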