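"""Shared fixtures: small grids and a cached weak-sphere measurement.

Everything is generated programmatically; module/session scoping keeps the
expensive forward simulations to a single run per session.
"""

import numpy as np
import pytest

from silicoclear import (
    GridSpec,
    ReconConfig,
    calibrate_qpgi_kernel,
    compute_qpgi_stack,
    make_homogeneous_sphere,
    make_illumination_grid,
    simulate_fieldset,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """A 32x32x16 grid at the simulation pitches (λ0/5 lateral, 2λ0/5 axial)."""
    return GridSpec(32, 32, 16, 0.2, 0.2, 0.4)


@pytest.fixture(scope="session")
def small_ills(small_grid):
    return make_illumination_grid(1.0, small_grid.k0 / 2.0, small_grid)


@pytest.fixture(scope="session")
def sphere_setup():
    """Weak sphere (δn = 0.002, D = 4λ0) with its simulated measurement,
    QPGI stack and calibrated kernel on a 64x64x32 grid, 37 illuminations."""
    grid = GridSpec(64, 64, 32, 0.2, 0.2, 0.4)
    ills = make_illumination_grid(1.0, grid.k0 / 3.5, grid)
    vol = make_homogeneous_sphere(grid, 4.0, grid.n_b + 0.002)
    fs = simulate_fieldset(vol, ills, na_det=1.0)
    stack = compute_qpgi_stack(fs, grid.z_slice_centers())
    kernel = calibrate_qpgi_kernel(ills, grid, nz_block=grid.nz)
    return {
        "grid": grid,
        "ills": ills,
        "vol": vol,
        "fields": fs,
        "stack": stack,
        "kernel": kernel,
    }


@pytest.fixture()
def fast_recon_cfg():
    """ADMM settings used across the synthetic-recovery tests: light
    regularization matched to the weak-contrast potentials and an inner CG
    budget that keeps runtimes reasonable."""
    return ReconConfig(
        tau=1e-6, xi=1e-5, rho=1e-3, iterations=30, cg_iterations=10
    )


def band_limited_slab(grid: GridSpec, amplitude: float, cutoff_frac: float,
                      seed: int) -> np.ndarray:
    """Random index contrast hard-band-limited laterally to
    ``cutoff_frac * k_b`` — screens built from it keep fields inside the
    propagating band, making BPM round trips exact."""
    from scipy import fft as sfft

    rng = np.random.default_rng(seed)
    dn = rng.standard_normal(grid.shape)
    mask = grid.transverse_k2() <= (cutoff_frac * grid.kb) ** 2
    spec = sfft.fft2(dn, axes=(1, 2))
    spec[:, ~mask] = 0.0
    dn = sfft.ifft2(spec, axes=(1, 2)).real
    return dn * (amplitude / np.abs(dn).max())
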