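"""Scalar wave simulation: plane-wave illumination, angular-spectrum
propagation, the multi-slice beam propagation method (BPM), and a small-scale
Lippmann–Schwinger solver used as an independent full-wave reference.

The BPM alternates non-paraxial free-space diffraction over one slice pitch
with a thin phase screen per slice,

    u(z + Δz) = O(z + Δz) · P_Δz{u(z)},
    P_Δz = F⁻¹ exp(i √(k_b² − |k_t|²) Δz) F,
    O    = exp(i k0 δn(r_t, z) α Δz),

where α = k_b / √(k_b² − |k_in,t|²) = 1/cosθ_in is the obliquity factor that
corrects the per-slice phase accumulation for oblique incidence.
Backpropagation applies the exact algebraic inverse (conjugate screens in
reverse order, inverted propagator), so a forward-then-backward pass through
any slab is the identity on the propagating band.

Evanescent policy: transverse frequencies with |k_t| > k_b are zeroed during
propagation, which keeps backpropagation free of exponential blow-up.

Lateral boundaries are FFT-periodic throughout.  Illumination wavevectors are
snapped onto the lateral FFT grid of the simulation window so that every
incident plane wave is exactly periodic on it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import fft as sfft
from scipy.sparse.linalg import LinearOperator, lgmres

from .core import GridSpec, RIVolume, potential_from_ri

__all__ = [
    "Illumination",
    "IlluminationSet",
    "ComplexField",
    "FieldSet",
    "make_illumination_grid",
    "obliquity_factor",
    "angular_spectrum_propagate",
    "apply_na_filter",
    "bpm_forward",
    "bpm_backpropagate",
    "simulate_fieldset",
    "solve_lippmann_schwinger",
]

_LS_MAX_VOXELS = 64**3  # guard for the dense-ish Lippmann-Schwinger solver


# ---------------------------------------------------------------------------
# illumination
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Illumination:
    """One incident plane wave, |k| = k_b with forward-going kz > 0."""

    kx: float
    ky: float
    kz: float
    index: int = 0

    @property
    def kt2(self) -> float:
        return self.kx**2 + self.ky**2


@dataclasses.dataclass
class IlluminationSet:
    illuminations: list[Illumination]
    na_max: float
    grid: GridSpec

    def __len__(self) -> int:
        return len(self.illuminations)

    def __iter__(self):
        return iter(self.illuminations)

    @property
    def normal(self) -> Illumination:
        for ill in self.illuminations:
            if ill.kx == 0.0 and ill.ky == 0.0:
                return ill
        raise ValueError("no normal-incidence illumination present")

    def k_array(self) -> np.ndarray:
        return np.array([[i.kx, i.ky, i.kz] for i in self.illuminations])


def make_illumination_grid(
    na_max: float,
    grid_spacing: float,
    grid: GridSpec,
    snap: bool = True,
) -> IlluminationSet:
    """Plane waves on a square k-space grid inside the illumination NA.

    Transverse wavevectors are laid out on a square grid of pitch
    ``grid_spacing`` centered at zero and retained iff
    ``sqrt(kx² + ky²) <= na_max * k0``.  With ``snap=True`` (default) each
    retained wavevector is moved to the nearest lateral FFT bin of ``grid``
    and duplicates are removed, so the resulting plane waves are periodic on
    the simulation window.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not (0 < na_max <= grid.n_b):
        raise ValueError("need 0 < NA_max <= n_b")
    k0 = grid.k0
    kb = grid.kb
    kmax = na_max * k0
    m = int(np.floor(kmax / grid_spacing + 1e-9))
    dkx = 2.0 * np.pi / (grid.nx * grid.dx)
    dky = 2.0 * np.pi / (grid.ny * grid.dy)
    seen: set[tuple[int, int]] = set()
    records: list[tuple[float, float, float, float]] = []
    for j in range(-m, m + 1):
        for i in range(-m, m + 1):
            kx = i * grid_spacing
            ky = j * grid_spacing
            if np.hypot(kx, ky) > kmax * (1 + 1e-12):
                continue
            if snap:
                bx = int(np.rint(kx / dkx))
                by = int(np.rint(ky / dky))
                if (bx, by) in seen:
                    continue
                seen.add((bx, by))
                kx = bx * dkx
                ky = by * dky
            kt2 = kx * kx + ky * ky
            if kt2 >= kb * kb:
                continue  # snapped outside the propagating band
            kz = float(np.sqrt(kb * kb - kt2))
            records.append((np.hypot(kx, ky), kx, ky, kz))
    records.sort(key=lambda r: (round(r[0], 9), round(r[1], 9), round(r[2], 9)))
    ills = [
        Illumination(kx=r[1], ky=r[2], kz=r[3], index=i)
        for i, r in enumerate(records)
    ]
    ill_set = IlluminationSet(ills, na_max=na_max, grid=grid)
    ill_set.normal  # raises if missing
    return ill_set


def obliquity_factor(ill: Illumination, kb: float) -> float:
    """α = k_b / √(k_b² − |k_in,t|²) = 1/cosθ_in."""
    kt2 = ill.kt2
    if kt2 >= kb * kb:
        raise ValueError("transverse wavevector at or beyond the medium wavenumber")
    return kb / np.sqrt(kb * kb - kt2)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComplexField:
    """A 2D complex amplitude at a stated z-plane for one illumination."""

    u: np.ndarray
    z: float
    grid: GridSpec
    illumination: Illumination
    carrier_removed: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("field shape does not match lateral grid")

    def copy(self) -> "ComplexField":
        return dataclasses.replace(self, u=self.u.copy())


@dataclasses.dataclass
class FieldSet:
    """Fields for all illuminations, sharing one reference plane."""

    fields: list[ComplexField]

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("empty field set")
        z0 = self.fields[0].z
        g0 = self.fields[0].grid
        for f in self.fields:
            if abs(f.z - z0) > 1e-9 * g0.dz or f.grid.shape[1:] != g0.shape[1:]:
                raise ValueError("fields must share grid and z-plane")

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)

    @property
    def z(self) -> float:
        return self.fields[0].z

    @property
    def grid(self) -> GridSpec:
        return self.fields[0].grid

    def copy(self) -> "FieldSet":
        return FieldSet([f.copy() for f in self.fields])


def plane_wave(grid: GridSpec, ill: Illumination, z: float = 0.0) -> ComplexField:
    """The incident plane wave ``exp(i k·r)`` sampled at plane ``z``."""
    x = grid.x_coords()
    y = grid.y_coords()
    phase = ill.kx * x[None, :] + ill.ky * y[:, None] + ill.kz * z
    return ComplexField(np.exp(1j * phase), z=z, grid=grid, illumination=ill)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _kz_and_mask(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    kt2 = grid.transverse_k2()
    kb2 = grid.kb**2
    prop = kt2 <= kb2
    kz = np.sqrt(np.maximum(kb2 - kt2, 0.0))
    return kz, prop


def propagation_phase(grid: GridSpec, dz: float) -> np.ndarray:
    """Spectral transfer function of P_Δz with evanescent components zeroed."""
    kz, prop = _kz_and_mask(grid)
    h = np.exp(1j * kz * dz)
    h[~prop] = 0.0
    return h


def angular_spectrum_propagate(f: ComplexField, dz: float) -> ComplexField:
    """Free-space propagation by a signed distance ``dz``.

    ``dz = 0`` is an exact identity (no evanescent filtering is applied).
    """
    if not np.all(np.isfinite(f.u)):
        raise ValueError("non-finite field")
    if dz == 0.0:
        return f.copy()
    spec = sfft.fft2(f.u)
    spec *= propagation_phase(f.grid, dz)
    out = sfft.ifft2(spec)
    return dataclasses.replace(f, u=out, z=f.z + dz)


def apply_na_filter(f: ComplexField, na_det: float) -> ComplexField:
    """Hard circular low-pass at ``na_det * k0`` modelling the detection lens."""
    kt2 = f.grid.transverse_k2()
    cutoff = (na_det * f.grid.k0) ** 2
    spec = sfft.fft2(f.u)
    spec[kt2 > cutoff * (1 + 1e-12)] = 0.0
    return dataclasses.replace(f, u=sfft.ifft2(spec))


def _edge_taper(grid: GridSpec, width: int) -> np.ndarray:
    """Cosine taper going to zero over ``width`` voxels at the lateral edges."""
    def ramp(n: int) -> np.ndarray:
        w = np.ones(n)
        if width > 0:
            t = 0.5 * (1 - np.cos(np.pi * (np.arange(width) + 0.5) / width))
            w[:width] = t
            w[-width:] = t[::-1]
        return w

    return ramp(grid.ny)[:, None] * ramp(grid.nx)[None, :]


def _bpm_screens(
    vol: RIVolume, alpha: float, dz: float, taper: np.ndarray | None
) -> np.ndarray:
    """Per-slice phase screens exp(i k0 δn α Δz), shape (nz, ny, nx)."""
    dn = vol.delta_n
    if taper is not None:
        dn = dn * taper[None, :, :]
    return np.exp(1j * vol.grid.k0 * dn * alpha * dz)


def bpm_forward(
    vol: RIVolume,
    ills: IlluminationSet | Sequence[Illumination],
    dz: float | None = None,
    apodization: int = 0,
) -> FieldSet:
    """Propagate each incident plane wave through ``vol`` with the BPM.

    The incident wave enters at z = 0; the returned fields sit at the exit
    (detection-side) boundary z = nz·dz.  ``dz`` must equal the volume pitch
    or an integer subdivision of it.  ``apodization`` > 0 applies a cosine
    taper of that many voxels to the *object contrast* near the lateral
    edges (the slice operators stay unitary).
    """
    grid = vol.grid
    if dz is None:
        dz = grid.dz
    nsub = grid.dz / dz
    if abs(nsub - round(nsub)) > 1e-9:
        raise ValueError("dz must be an integer subdivision of the grid pitch")
    nsub = int(round(nsub))
    taper = _edge_taper(grid, apodization) if apodization > 0 else None
    prop = propagation_phase(grid, dz)
    out: list[ComplexField] = []
    ill_list = list(ills)
    for ill in ill_list:
        alpha = obliquity_factor(ill, grid.kb)
        screens = _bpm_screens(vol, alpha, dz, taper)
        u = plane_wave(grid, ill, z=0.0).u
        for iz in range(grid.nz):
            for _ in range(nsub):
                u = sfft.ifft2(sfft.fft2(u) * prop)
                u = u * screens[iz]
        out.append(
            ComplexField(u, z=grid.nz * grid.dz, grid=grid, illumination=ill)
        )
    return FieldSet(out)


def bpm_backpropagate(
    fs: FieldSet,
    slab: RIVolume,
    dz: float | None = None,
    apodization: int = 0,
) -> FieldSet:
    """Backpropagate fields from the slab's detection-side boundary to its
    illumination-side boundary,

        u(z − Δz) = O* · P_{−Δz}{u(z)},

    applied as the exact inverse of :func:`bpm_forward` (conjugate screens in
    reverse slice order).  The returned fields carry ``z`` reduced by the
    slab thickness.
    """
    grid = slab.grid
    if fs.grid.shape[1:] != grid.shape[1:] or fs.grid.dx != grid.dx:
        raise ValueError("field grid does not match slab grid")
    if dz is None:
        dz = grid.dz
    nsub = grid.dz / dz
    if abs(nsub - round(nsub)) > 1e-9:
        raise ValueError("dz must be an integer subdivision of the grid pitch")
    nsub = int(round(nsub))
    taper = _edge_taper(grid, apodization) if apodization > 0 else None
    prop = propagation_phase(grid, -dz)
    out: list[ComplexField] = []
    for f in fs:
        alpha = obliquity_factor(f.illumination, grid.kb)
        screens = _bpm_screens(slab, alpha, dz, taper)
        u = f.u
        for iz in range(grid.nz - 1, -1, -1):
            for _ in range(nsub):
                u = u * np.conj(screens[iz])
                u = sfft.ifft2(sfft.fft2(u) * prop)
        out.append(
            dataclasses.replace(f, u=u, z=f.z - grid.nz * grid.dz)
        )
    return FieldSet(out)


def simulate_fieldset(
    vol: RIVolume,
    ills: IlluminationSet,
    na_det: float = 1.0,
    apodization: int = 0,
) -> FieldSet:
    """Forward-simulate the angle-scanned measurement: BPM through the
    volume followed by the detection-NA low-pass at the exit plane."""
    fs = bpm_forward(vol, ills, apodization=apodization)
    return FieldSet([apply_na_filter(f, na_det) for f in fs])


# ---------------------------------------------------------------------------
# Lippmann-Schwinger reference solver
# ---------------------------------------------------------------------------

def _truncated_greens_spectrum(grid: GridSpec, pshape: tuple[int, int, int]):
    """FFT of the radially truncated Helmholtz kernel e^{i k_b r}/(4π r).

    Truncating the kernel at a radius covered by the zero-padded box makes
    the circular convolution agree with the aperiodic one exactly for
    sources and targets inside the original box.  The r = 0 voxel is
    assigned the analytic average of the kernel over a sphere of equal
    volume.
    """
    nzp, nyp, nxp = pshape
    kb = grid.kb
    z = sfft.fftfreq(nzp) * nzp * grid.dz
    y = sfft.fftfreq(nyp) * nyp * grid.dy
    x = sfft.fftfreq(nxp) * nxp * grid.dx
    r = np.sqrt(
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    rcut = 0.5 * min(nzp * grid.dz, nyp * grid.dy, nxp * grid.dx)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.exp(1j * kb * r) / (4.0 * np.pi * r)
    g[r > rcut] = 0.0
    # singular voxel: (1/dV) ∫_ball e^{ikr}/(4πr) dV over the equal-volume ball
    dv = grid.voxel_volume
    a = (3.0 * dv / (4.0 * np.pi)) ** (1.0 / 3.0)
    integral = (np.exp(1j * kb * a) * (1j * kb * a - 1.0) + 1.0) / (1j * kb) ** 2
    g[0, 0, 0] = integral / dv
    return sfft.fftn(g) * dv


def _damped_greens_spectrum(grid: GridSpec, pshape: tuple[int, int, int]):
    """Spectral Green's function 1/(k_b² − |k|² − iε) with ε tied to the
    padded box size (damping length of order the box)."""
    nzp, nyp, nxp = pshape
    kz = 2 * np.pi * sfft.fftfreq(nzp, d=grid.dz)
    ky = 2 * np.pi * sfft.fftfreq(nyp, d=grid.dy)
    kx = 2 * np.pi * sfft.fftfreq(nxp, d=grid.dx)
    k2 = (
        kz[:, None, None] ** 2 + ky[None, :, None] ** 2 + kx[None, None, :] ** 2
    )
    lmax = max(nzp * grid.dz, nyp * grid.dy, nxp * grid.dx)
    eps = 2.0 * grid.kb * (2.0 * np.pi / lmax)
    return 1.0 / (grid.kb**2 - k2 - 1j * eps)


class ConvergenceError(RuntimeError):
    """Iterative solve failed; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


def solve_lippmann_schwinger(
    vol: RIVolume,
    ill: Illumination,
    tol: float = 1e-6,
    maxiter: int = 300,
    greens_form: str = "truncated",
) -> ComplexField:
    """Solve ``u = u_in + G * (V u)`` and return the field at the
    detection-side plane z = nz·dz.

    The volumetric solve uses an LGMRES iteration with the convolutional
    Green's function evaluated on a 2× zero-padded grid.  The exit field is
    then synthesized by angular-spectrum propagation of each source slice
    ``V·u`` to the detection plane — exact given the volumetric solution.

    Restricted to small volumes (≤ 64³ voxels); this is a reference oracle,
    not a production forward model.
    """
    grid = vol.grid
    nvox = grid.nx * grid.ny * grid.nz
    if nvox > _LS_MAX_VOXELS:
        raise ValueError(
            f"volume has {nvox} voxels; Lippmann-Schwinger solver is "
            f"guarded to <= {_LS_MAX_VOXELS}"
        )
    V = potential_from_ri(vol)
    pshape = tuple(sfft.next_fast_len(2 * s) for s in grid.shape)
    if greens_form == "truncated":
        ghat = _truncated_greens_spectrum(grid, pshape)
    elif greens_form == "damped":
        ghat = _damped_greens_spectrum(grid, pshape)
    else:
        raise ValueError(f"unknown greens_form {greens_form!r}")

    shape = grid.shape

    def convolve(w: np.ndarray) -> np.ndarray:
        wp = np.zeros(pshape, dtype=complex)
        wp[: shape[0], : shape[1], : shape[2]] = w
        out = sfft.ifftn(sfft.fftn(wp) * ghat)
        return out[: shape[0], : shape[1], : shape[2]]

    def matvec(uflat: np.ndarray) -> np.ndarray:
        u = uflat.reshape(shape)
        return (u - convolve(V * u)).ravel()

    # incident wave sampled at slice centers
    x = grid.x_coords()
    y = grid.y_coords()
    zc = grid.z_slice_centers()
    u_in = np.exp(
        1j
        * (
            ill.kx * x[None, None, :]
            + ill.ky * y[None, :, None]
            + ill.kz * zc[:, None, None]
        )
    )
    if not np.any(V):
        u_sol = u_in
    else:
        A = LinearOperator(
            (nvox, nvox), matvec=matvec, dtype=complex
        )
        u_sol_flat, info = lgmres(
            A, u_in.ravel(), x0=u_in.ravel(), rtol=tol, atol=0.0,
            maxiter=maxiter,
        )
        res = np.linalg.norm(matvec(u_sol_flat) - u_in.ravel()) / np.linalg.norm(
            u_in
        )
        if info != 0 and res > 10 * tol:
            raise ConvergenceError("Lippmann-Schwinger solve did not converge", res)
        u_sol = u_sol_flat.reshape(shape)

    # exit field at the detection-side boundary
    z_d = grid.nz * grid.dz
    kz, prop = _kz_and_mask(grid)
    spec = np.zeros((grid.ny, grid.nx), dtype=complex)
    src = V * u_sol
    for iz in range(grid.nz):
        dzp = z_d - zc[iz]
        g2d = np.where(prop, 1j * np.exp(1j * kz * dzp) / (2.0 * np.maximum(kz, 1e-30)), 0.0)
        spec += sfft.fft2(src[iz]) * g2d * grid.dz
    u_exit = sfft.ifft2(spec)
    u_exit += np.exp(
        1j * (ill.kx * x[None, :] + ill.ky * y[:, None] + ill.kz * z_d)
    )
    return ComplexField(u_exit, z=z_d, grid=grid, illumination=ill)
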