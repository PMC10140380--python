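"""Linear QPGI operator and the ADMM inversion."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silicoclear import (
    GridSpec,
    ReconConfig,
    RIVolume,
    admm_reconstruct,
    apply_forward_operator,
    calibrate_qpgi_kernel,
    potential_from_ri,
    ri_from_potential,
)
from silicoclear.fieldsynth import QPGIStack
from silicoclear.recon import QPGIOperator, _grad, _grad_adjoint


class TestPotentialConversion:
    def test_background_maps_to_zero(self, small_grid):
        vol = RIVolume(small_grid, np.full(small_grid.shape, small_grid.n_b))
        assert np.allclose(potential_from_ri(vol), 0.0)

    def test_hand_evaluated_value(self):
        # V = k_b^2 [(n/n_b)^2 - 1] at n = 1.370, n_b = 1.333, λ0 = 0.6328 µm
        grid = GridSpec(1, 1, 1, 0.1, 0.1, 0.1, wavelength=0.6328, n_b=1.333)
        vol = RIVolume(grid, np.full((1, 1, 1), 1.370))
        kb = 2 * np.pi * 1.333 / 0.6328
        expected = kb**2 * ((1.370 / 1.333) ** 2 - 1.0)
        assert potential_from_ri(vol)[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip(self, seed):
        grid = GridSpec(8, 8, 8, 0.2, 0.2, 0.2)
        rng = np.random.default_rng(seed)
        n = 1.0 + rng.uniform(0.3, 0.5, grid.shape)
        vol = RIVolume(grid, n)
        back = ri_from_potential(potential_from_ri(vol), grid)
        assert np.allclose(back.n, n, atol=1e-12)

    def test_inverse_rejects_imaginary_index(self, small_grid):
        V = np.full(small_grid.shape, -2.0 * small_grid.kb**2)
        with pytest.raises(ValueError, match="imaginary|real"):
            ri_from_potential(V, small_grid)


class TestKernel:
    def test_zero_scatterer_gives_zero_response(self, sphere_setup):
        px, py = apply_forward_operator(
            np.zeros(QPGIOperator(sphere_setup["kernel"]).shape_in),
            sphere_setup["kernel"],
        )
        assert not px.any() and not py.any()

    def test_calibration_is_born_linear(self, small_grid):
        from silicoclear import make_illumination_grid
        from silicoclear.recon import _impulse_stack_response

        ills = make_illumination_grid(1.0, small_grid.k0 / 2, small_grid)
        px1, _, V1 = _impulse_stack_response(
            small_grid, ills, small_grid.dx, small_grid.dy, 1.0, 1e-4
        )
        px2, _, V2 = _impulse_stack_response(
            small_grid, ills, small_grid.dx, small_grid.dy, 1.0, 5e-5
        )
        ref = np.abs(px1 / V1).max()
        assert np.abs(px1 / V1 - px2 / V2).max() < 0.01 * ref

    def test_four_fold_symmetry_swaps_axes(self, sphere_setup):
        # H_y equals H_x with the x and y axes exchanged
        kern = sphere_setup["kernel"]
        from scipy import fft as sfft

        hx = sfft.irfftn(kern.H_x, s=kern.fft_shape)
        hy = sfft.irfftn(kern.H_y, s=kern.fft_shape)
        assert np.allclose(hy, np.swapaxes(hx, 1, 2), atol=1e-6 * np.abs(hx).max())

    def test_analytic_mode_has_provenance(self, small_grid):
        from silicoclear import make_illumination_grid

        ills = make_illumination_grid(1.0, small_grid.k0 / 2, small_grid)
        kern = calibrate_qpgi_kernel(
            ills, small_grid, nz_block=small_grid.nz, mode="analytic"
        )
        assert kern.provenance == "analytic"
        assert np.all(np.isfinite(kern.H_x))


class TestForwardOperator:
    def test_linearity_and_superposition(self, sphere_setup):
        kern = sphere_setup["kernel"]
        op = QPGIOperator(kern)
        rng = np.random.default_rng(3)
        v1 = rng.random(op.shape_in)
        v2 = rng.random(op.shape_in)
        ax1, ay1 = op.forward(v1)
        ax2, ay2 = op.forward(v2)
        axs, ays = op.forward(v1 + v2)
        assert np.allclose(axs, ax1 + ax2, atol=1e-10)
        assert np.allclose(ays, ay1 + ay2, atol=1e-10)

    def test_adjoint_consistency(self, sphere_setup):
        op = QPGIOperator(sphere_setup["kernel"])
        rng = np.random.default_rng(4)
        v = rng.random(op.shape_in)
        rx, ry = rng.random(op.shape_in), rng.random(op.shape_in)
        fx, fy = op.forward(v)
        lhs = np.sum(fx * rx) + np.sum(fy * ry)
        rhs = np.sum(v * op.adjoint(rx, ry))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_matches_full_wave_qpgi_within_gate(self, sphere_setup):
        # weak sphere: linear prediction vs BPM-simulated stack, <= 20%
        V = potential_from_ri(sphere_setup["vol"])
        px, py = apply_forward_operator(V, sphere_setup["kernel"])
        stack = sphere_setup["stack"]
        err = np.linalg.norm(px - stack.psi_x) / np.linalg.norm(stack.psi_x)
        assert err <= 0.20

    def test_lateral_shift_equivariance(self, sphere_setup):
        kern = sphere_setup["kernel"]
        op = QPGIOperator(kern)
        rng = np.random.default_rng(5)
        v = rng.random(op.shape_in)
        sx, sy = 7, 11
        fx, _ = op.forward(v)
        fx_shifted, _ = op.forward(np.roll(v, (sy, sx), axis=(1, 2)))
        assert np.allclose(fx_shifted, np.roll(fx, (sy, sx), axis=(1, 2)), atol=1e-10)


class TestADMM:
    def test_zero_data_gives_background(self, sphere_setup, fast_recon_cfg):
        kern = sphere_setup["kernel"]
        shape = QPGIOperator(kern).shape_in
        stack = QPGIStack(
            psi_x=np.zeros(shape), psi_y=np.zeros(shape),
            shear_x=kern.shear_x, shear_y=kern.shear_y,
            z_planes=np.arange(shape[0]),
        )
        cfg = dataclasses.replace(fast_recon_cfg, iterations=5)
        vol, trace = admm_reconstruct(stack, kern, cfg)
        assert np.allclose(vol.n, kern.grid.n_b, atol=1e-12)

    def test_defaults_match_reference_protocol(self):
        cfg = ReconConfig()
        assert cfg.tau == pytest.approx(7.5e-2)
        assert cfg.xi == pytest.approx(0.1)
        assert cfg.iterations == 50

    def test_output_at_least_background_and_objective_decreases(
        self, sphere_setup, fast_recon_cfg
    ):
        vol, trace = admm_reconstruct(
            sphere_setup["stack"], sphere_setup["kernel"], fast_recon_cfg
        )
        assert np.min(vol.n.real) >= sphere_setup["grid"].n_b - 1e-12
        assert trace[-1] <= trace[0]

    def test_least_squares_limit_drives_residual_to_zero(self, sphere_setup):
        # τ = ξ = 0, no constraint, on data generated by the operator itself
        kern = sphere_setup["kernel"]
        op = QPGIOperator(kern)
        rng = np.random.default_rng(6)
        from scipy import ndimage

        v_true = ndimage.gaussian_filter(rng.random(op.shape_in), 2.0)
        px, py = op.forward(v_true)
        stack = QPGIStack(
            psi_x=px, psi_y=py, shear_x=kern.shear_x, shear_y=kern.shear_y,
            z_planes=np.arange(op.shape_in[0]),
        )
        cfg = ReconConfig(
            tau=0.0, xi=0.0, rho=1e-4, iterations=15, cg_iterations=30,
            nonneg=False,
        )
        v_hat, trace = admm_reconstruct(stack, kern, cfg, return_potential=True)
        qx, qy = op.forward(v_hat)
        res = np.linalg.norm(qx - px) / np.linalg.norm(px)
        assert res < 0.05

    def test_nan_data_aborts_with_diagnostic(self, sphere_setup, fast_recon_cfg):
        kern = sphere_setup["kernel"]
        shape = QPGIOperator(kern).shape_in
        bad = np.zeros(shape)
        bad[0, 0, 0] = np.nan
        stack = QPGIStack(
            psi_x=bad, psi_y=np.zeros(shape), shear_x=kern.shear_x,
            shear_y=kern.shear_y, z_planes=np.arange(shape[0]),
        )
        with pytest.raises(RuntimeError, match="non-finite"):
            admm_reconstruct(stack, kern, fast_recon_cfg)


def test_gradient_adjoint_pair():
    rng = np.random.default_rng(7)
    x = rng.random((6, 7, 8))
    g = rng.random((3, 6, 7, 8))
    assert np.sum(_grad(x) * g) == pytest.approx(
        np.sum(x * _grad_adjoint(g)), rel=1e-12
    )
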