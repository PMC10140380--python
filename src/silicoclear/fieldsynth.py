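"""Quantitative phase (gradient) image synthesis from angle-scanned fields.

Given complex fields u(r, k_in^j) the carrier is first removed,

    ū(r, k_in^j) = u(r, k_in^j) exp(−i k_in^j · r),

and the sheared incoherent accumulation

    W̄(r) = (1/N_in) Σ_j ū_j(r) ū_j*(r + δr)

is formed; the quantitative phase *gradient* image (QPGI) is arg W̄.  Because
every illumination contributes an intensity-like product, the accumulation is
incoherent and exhibits optical sectioning: refocusing the fields to a stack
of z-planes and accumulating per plane yields a z-stack in which a scatterer
appears only near its true depth, unlike single-field quantitative phase
imaging (QPI) whose axial response is heavy-tailed.

The shift by the shear vector δr uses Fourier interpolation, so sub-voxel
shears are exact for band-limited fields.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .core import GridSpec
from .wavesim import ComplexField, FieldSet, propagation_phase

__all__ = [
    "QPGIStack",
    "normalize_field",
    "qpgi_accumulate",
    "compute_qpgi_stack",
    "compute_qpi",
]


@dataclasses.dataclass
class QPGIStack:
    """Paired x-/y-sheared phase-gradient stacks over a block's z-planes."""

    psi_x: np.ndarray  # (nz, ny, nx), radians, in (-pi, pi]
    psi_y: np.ndarray
    shear_x: float
    shear_y: float
    z_planes: np.ndarray

    def __post_init__(self) -> None:
        self.psi_x = np.asarray(self.psi_x, dtype=float)
        self.psi_y = np.asarray(self.psi_y, dtype=float)
        self.z_planes = np.asarray(self.z_planes, dtype=float)
        if self.psi_x.shape != self.psi_y.shape:
            raise ValueError("psi_x and psi_y must share a shape")
        if self.psi_x.shape[0] != len(self.z_planes):
            raise ValueError("stack depth must match z_planes")
        if self.shear_x == 0.0 or self.shear_y == 0.0:
            raise ValueError("shear magnitudes must be nonzero")


def _carrier(grid: GridSpec, ill, z: float) -> np.ndarray:
    x = grid.x_coords()
    y = grid.y_coords()
    return np.exp(
        -1j * (ill.kx * x[None, :] + ill.ky * y[:, None] + ill.kz * z)
    )


def normalize_field(f: ComplexField) -> ComplexField:
    """Remove the plane-wave carrier exactly once (guarded by a flag)."""
    if f.carrier_removed:
        raise ValueError("carrier already removed from this field")
    u = f.u * _carrier(f.grid, f.illumination, f.z)
    return dataclasses.replace(f, u=u, carrier_removed=True)


def _fourier_shift_phase(grid: GridSpec, dxs: float, dys: float) -> np.ndarray:
    kx = grid.kx_grid()
    ky = grid.ky_grid()
    return np.exp(1j * (ky[:, None] * dys + kx[None, :] * dxs))


def qpgi_accumulate(
    fields: Sequence[ComplexField] | FieldSet,
    shear: tuple[float, float],
) -> np.ndarray:
    """The incoherent accumulation W̄ for one z-plane and one shear vector.

    ``fields`` must already be carrier-normalized; returns the complex W̄
    (take ``np.angle`` for the QPGI).
    """
    flist = list(fields)
    if not flist:
        raise ValueError("need at least one field")
    dxs, dys = shear
    if dxs == 0.0 and dys == 0.0:
        raise ValueError("shear vector must be nonzero")
    grid = flist[0].grid
    lx, ly, _ = grid.extent
    if abs(dxs) > lx or abs(dys) > ly:
        raise ValueError("shear larger than the field extent")
    shift = _fourier_shift_phase(grid, dxs, dys)
    acc = np.zeros((grid.ny, grid.nx), dtype=complex)
    for f in flist:
        if not f.carrier_removed:
            raise ValueError("fields must be carrier-normalized first")
        shifted = sfft.ifft2(sfft.fft2(f.u) * shift)
        acc += f.u * np.conj(shifted)
    return acc / len(flist)


def compute_qpgi_stack(
    fs: FieldSet,
    z_planes: Sequence[float],
    shear_x: float | None = None,
    shear_y: float | None = None,
) -> QPGIStack:
    """Digitally refocus the field set to each z-plane and accumulate the
    x- and y-sheared QPGI there.

    Refocusing uses homogeneous-medium (free-space) angular-spectrum
    propagation from the fields' common reference plane.  Default shears are
    one lateral voxel pitch along each axis.
    """
    grid = fs.grid
    if shear_x is None:
        shear_x = grid.dx
    if shear_y is None:
        shear_y = grid.dy
    z_planes = np.asarray(list(z_planes), dtype=float)
    nz = len(z_planes)
    psi_x = np.empty((nz, grid.ny, grid.nx))
    psi_y = np.empty((nz, grid.ny, grid.nx))
    shift_x = _fourier_shift_phase(grid, shear_x, 0.0)
    shift_y = _fourier_shift_phase(grid, 0.0, shear_y)
    # precompute each field's spectrum at the reference plane once
    specs = [sfft.fft2(f.u) for f in fs]
    kz_mask = propagation_phase(grid, 1.0)  # unit-distance phase, band mask
    kz = np.angle(kz_mask)
    band = kz_mask != 0
    x = grid.x_coords()
    y = grid.y_coords()
    for iz, z in enumerate(z_planes):
        dz = z - fs.z
        prop = np.where(band, np.exp(1j * kz * dz), 0.0)
        wx = np.zeros((grid.ny, grid.nx), dtype=complex)
        wy = np.zeros((grid.ny, grid.nx), dtype=complex)
        for f, spec in zip(fs, specs):
            ill = f.illumination
            spec_z = spec * prop
            carrier = np.exp(
                -1j
                * (ill.kx * x[None, :] + ill.ky * y[:, None] + ill.kz * z)
            )
            u_bar = sfft.ifft2(spec_z) * carrier
            ux = sfft.ifft2(spec_z * shift_x)
            uy = sfft.ifft2(spec_z * shift_y)
            # carrier of the sheared sample evaluated at r + δr
            ux_bar = ux * carrier * np.exp(-1j * ill.kx * shear_x)
            uy_bar = uy * carrier * np.exp(-1j * ill.ky * shear_y)
            wx += u_bar * np.conj(ux_bar)
            wy += u_bar * np.conj(uy_bar)
        psi_x[iz] = np.angle(wx / len(fs))
        psi_y[iz] = np.angle(wy / len(fs))
    return QPGIStack(
        psi_x=psi_x, psi_y=psi_y, shear_x=shear_x, shear_y=shear_y,
        z_planes=z_planes,
    )


def compute_qpi(f: ComplexField) -> np.ndarray:
    """Principal-value phase of the carrier-normalized field (no unwrapping)."""
    if f.carrier_removed:
        return np.angle(f.u)
    return np.angle(f.u * _carrier(f.grid, f.illumination, f.z))
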