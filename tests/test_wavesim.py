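"""Propagation physics: illumination grids, angular spectrum, BPM and the
Lippmann-Schwinger reference solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silicoclear import (
    GridSpec,
    Illumination,
    RIVolume,
    angular_spectrum_propagate,
    bpm_backpropagate,
    bpm_forward,
    make_homogeneous_sphere,
    make_illumination_grid,
    obliquity_factor,
    solve_lippmann_schwinger,
)
from silicoclear.wavesim import FieldSet, plane_wave, propagation_phase

from conftest import band_limited_slab


class TestIlluminationGrid:
    def test_coarse_spacing_gives_five_beams(self, small_grid):
        # spacing = NA*k0: normal plus the four axis-aligned extremes
        ills = make_illumination_grid(
            0.5, 0.5 * small_grid.k0, small_grid, snap=False
        )
        assert len(ills) == 5
        kts = sorted(round(i.kt2, 9) for i in ills)
        assert kts[0] == 0.0 and len({k for k in kts[1:]}) == 1

    def test_normal_incidence_present_with_unit_obliquity(self, small_ills, small_grid):
        ill = small_ills.normal
        assert obliquity_factor(ill, small_grid.kb) == pytest.approx(1.0)

    def test_count_matches_disc_lattice_enumeration(self, small_grid):
        na = 0.9
        spacing = na * small_grid.k0 / 10.0
        ills = make_illumination_grid(na, spacing, small_grid, snap=False)
        kmax = na * small_grid.k0
        m = int(np.floor(kmax / spacing + 1e-9))
        brute = sum(
            1
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            if np.hypot(i * spacing, j * spacing) <= kmax * (1 + 1e-12)
        )
        assert len(ills) == brute

    def test_snapped_wavevectors_lie_on_fft_grid(self, small_ills, small_grid):
        dk = 2 * np.pi / (small_grid.nx * small_grid.dx)
        for ill in small_ills:
            assert abs(ill.kx / dk - round(ill.kx / dk)) < 1e-9

    def test_no_duplicates(self, small_ills):
        ks = {(round(i.kx, 9), round(i.ky, 9)) for i in small_ills}
        assert len(ks) == len(small_ills)


class TestObliquity:
    def test_sixty_degrees_doubles(self):
        kb = 2 * np.pi * 1.333
        ill = Illumination(kx=kb * np.sin(np.pi / 3), ky=0.0, kz=kb * 0.5)
        assert obliquity_factor(ill, kb) == pytest.approx(2.0, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(theta=st.floats(0.0, 1.3), phi=st.floats(0.0, 2 * np.pi))
    def test_matches_inverse_cosine_identity(self, theta, phi):
        kb = 2 * np.pi * 1.333
        kt = kb * np.sin(theta)
        ill = Illumination(
            kx=kt * np.cos(phi), ky=kt * np.sin(phi), kz=kb * np.cos(theta)
        )
        expected = 1.0 / np.cos(np.arcsin(min(kt / kb, 1.0)))
        assert obliquity_factor(ill, kb) == pytest.approx(expected, rel=1e-12)

    def test_rejects_evanescent(self):
        kb = 2 * np.pi * 1.333
        with pytest.raises(ValueError):
            obliquity_factor(Illumination(kx=1.1 * kb, ky=0.0, kz=0.0), kb)


class TestAngularSpectrum:
    def test_zero_distance_is_identity(self, small_grid, small_ills):
        f = plane_wave(small_grid, small_ills.normal)
        g = angular_spectrum_propagate(f, 0.0)
        assert np.array_equal(f.u, g.u)

    def test_round_trip_restores_propagating_band(self, small_grid, small_ills):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        f = plane_wave(small_grid, small_ills.normal)
        f.u = u
        once = angular_spectrum_propagate(f, 1.7)
        back = angular_spectrum_propagate(once, -1.7)
        # compare against the band-limited original
        from scipy import fft as sfft

        mask = propagation_phase(small_grid, 1.0) != 0
        u_band = sfft.ifft2(sfft.fft2(u) * mask)
        assert np.linalg.norm(back.u - u_band) < 1e-10 * np.linalg.norm(u_band)

    def test_plane_wave_accumulates_closed_form_phase(self, small_grid, small_ills):
        ill = max(small_ills, key=lambda i: i.kt2)
        f = plane_wave(small_grid, ill, z=0.0)
        g = angular_spectrum_propagate(f, 2.4)
        expected = f.u * np.exp(1j * ill.kz * 2.4)
        assert np.allclose(g.u, expected, atol=1e-10)

    def test_energy_conserved_on_band(self, small_grid, small_ills):
        f = plane_wave(small_grid, small_ills.normal)
        g = angular_spectrum_propagate(f, 3.3)
        assert np.linalg.norm(g.u) == pytest.approx(np.linalg.norm(f.u), rel=1e-10)


class TestBPM:
    def test_homogeneous_medium_gives_analytic_plane_waves(self, small_grid, small_ills):
        vol = RIVolume(small_grid, np.full(small_grid.shape, small_grid.n_b))
        fs = bpm_forward(vol, small_ills)
        for f in fs:
            expected = plane_wave(
                small_grid, f.illumination, z=small_grid.nz * small_grid.dz
            ).u
            assert np.allclose(f.u, expected, atol=1e-12)

    def test_thin_slab_phase_and_obliquity_scaling(self, small_grid, small_ills):
        # single-slice slab: on-axis phase k0*dn*t, scaled by 1/cos(theta)
        dn = 0.004
        n = np.full(small_grid.shape, small_grid.n_b)
        n[7] += dn
        vol = RIVolume(small_grid, n)
        fs = bpm_forward(vol, small_ills)
        t = small_grid.dz
        for f in fs:
            alpha = obliquity_factor(f.illumination, small_grid.kb)
            ref = plane_wave(
                small_grid, f.illumination, z=small_grid.nz * small_grid.dz
            ).u
            phase = np.angle(f.u / ref).mean()
            assert phase == pytest.approx(small_grid.k0 * dn * t * alpha, rel=1e-9)

    def test_forward_backward_identity_on_band_limited_slab(self, small_grid):
        ills = make_illumination_grid(0.3, 0.3 * small_grid.k0 / 1.5, small_grid)
        dn = band_limited_slab(small_grid, 0.003, 0.25, seed=1)
        vol = RIVolume(small_grid, small_grid.n_b + dn)
        fs = bpm_forward(vol, ills)
        back = bpm_backpropagate(fs, vol)
        for f in back:
            f0 = plane_wave(small_grid, f.illumination, 0.0)
            err = np.linalg.norm(f.u - f0.u) / np.linalg.norm(f0.u)
            assert err < 1e-8

    def test_backprop_through_empty_slab_is_free_space(self, small_grid, small_ills):
        vol = RIVolume(small_grid, np.full(small_grid.shape, small_grid.n_b))
        z_d = small_grid.nz * small_grid.dz
        fs = bpm_forward(vol, small_ills)
        back = bpm_backpropagate(fs, vol)
        for f_fwd, f_back in zip(fs, back):
            free = angular_spectrum_propagate(f_fwd, -z_d)
            assert np.allclose(f_back.u, free.u, atol=1e-10)

    def test_forward_is_linear_in_input_field(self, small_grid, small_ills):
        # superposing incident fields superposes outputs (fixed volume)
        rng = np.random.default_rng(2)
        vol = RIVolume(
            small_grid,
            small_grid.n_b + band_limited_slab(small_grid, 0.01, 0.3, seed=3),
        )
        from silicoclear.wavesim import _bpm_screens, propagation_phase as pp
        from scipy import fft as sfft

        prop = pp(small_grid, small_grid.dz)
        screens = _bpm_screens(vol, 1.0, small_grid.dz, None)

        def run(u):
            for iz in range(small_grid.nz):
                u = sfft.ifft2(sfft.fft2(u) * prop) * screens[iz]
            return u

        u1 = rng.standard_normal((32, 32)) * 1j + rng.standard_normal((32, 32))
        u2 = rng.standard_normal((32, 32)) * 1j + rng.standard_normal((32, 32))
        assert np.allclose(run(u1 + u2), run(u1) + run(u2), atol=1e-10)

    def test_wavefront_flattens_after_backprop_through_truth(self, small_grid):
        ills = make_illumination_grid(1.0, small_grid.k0 / 2, small_grid)
        vol = make_homogeneous_sphere(small_grid, 3.0, small_grid.n_b + 0.01)
        fs = bpm_forward(vol, ills)
        back = bpm_backpropagate(fs, vol)
        from silicoclear.fieldsynth import normalize_field

        def phase_std(fset):
            vals = []
            for f in fset:
                fn = normalize_field(f)
                vals.append(np.angle(fn.u).std())
            return np.mean(vals)

        assert phase_std(back) < phase_std(fs)


class TestLippmannSchwinger:
    def test_empty_potential_returns_incident_wave(self, small_grid, small_ills):
        vol = RIVolume(small_grid, np.full(small_grid.shape, small_grid.n_b))
        ill = small_ills.normal
        f = solve_lippmann_schwinger(vol, ill)
        expected = plane_wave(small_grid, ill, z=small_grid.nz * small_grid.dz).u
        assert np.allclose(f.u, expected, atol=1e-10)

    def test_scattered_field_linear_in_contrast(self):
        # Born limit: halving the contrast halves the scattered field
        grid = GridSpec(32, 32, 24, 0.2, 0.2, 0.2)
        ills = make_illumination_grid(1.0, grid.k0 / 2, grid)
        ill = ills.normal
        u_in = plane_wave(grid, ill, z=grid.nz * grid.dz).u
        norms = []
        for dn in (0.002, 0.001):
            vol = make_homogeneous_sphere(grid, 2.0, grid.n_b + dn)
            f = solve_lippmann_schwinger(vol, ill, tol=1e-10)
            norms.append(np.linalg.norm(f.u - u_in))
        assert norms[0] / norms[1] == pytest.approx(2.0, rel=0.02)

    def test_guard_rejects_large_volumes(self):
        grid = GridSpec(80, 80, 80, 0.2, 0.2, 0.2)
        vol = RIVolume(grid, np.full(grid.shape, grid.n_b))
        ill = Illumination(kx=0.0, ky=0.0, kz=grid.kb)
        with pytest.raises(ValueError, match="guard"):
            solve_lippmann_schwinger(vol, ill)


def test_potential_volume_fieldset_shape_contracts(small_grid, small_ills):
    vol = RIVolume(small_grid, np.full(small_grid.shape, small_grid.n_b))
    fs = bpm_forward(vol, small_ills)
    assert len(fs) == len(small_ills)
    assert fs.z == pytest.approx(small_grid.nz * small_grid.dz)
    with pytest.raises(ValueError):
        FieldSet([])
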