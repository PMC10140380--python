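"""Core containers: sampling grids, refractive-index volumes, potential maps.

All lengths are expressed in a single consistent unit.  In simulation-style
configurations that unit is the free-space wavelength ``λ0`` (so ``dx = 0.2``
means λ0/5); in experiment-style configurations it is micrometres with
``wavelength`` set to the physical λ0.  Nothing downstream cares which, as
long as ``wavelength`` and the pitches share the unit.

Axis convention: arrays are indexed ``[z, y, x]``; the illumination enters at
``z = 0`` and the detection plane sits at ``z = nz * dz`` (high z, "near the
detection lens").
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "GridSpec",
    "RIVolume",
    "potential_from_ri",
    "ri_from_potential",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry plus the optical constants attached to it.

    Parameters
    ----------
    nx, ny, nz
        Voxel counts along x, y, z.
    dx, dy, dz
        Voxel pitches (same unit as ``wavelength``).
    wavelength
        Free-space wavelength λ0.
    n_b
        Background (immersion medium) refractive index.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    wavelength: float = 1.0
    n_b: float = 1.333

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel pitches must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_b < 1:
            raise ValueError("background index must be >= 1")

    # -- optical constants -------------------------------------------------
    @property
    def k0(self) -> float:
        """Free-space wavenumber 2π/λ0."""
        return 2.0 * np.pi / self.wavelength

    @property
    def kb(self) -> float:
        """Wavenumber in the medium, 2π n_b / λ0."""
        return 2.0 * np.pi * self.n_b / self.wavelength

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return (self.nz, self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent ``(Lx, Ly, Lz)``."""
        return (self.nx * self.dx, self.ny * self.dy, self.nz * self.dz)

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    def x_coords(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    def y_coords(self) -> np.ndarray:
        return np.arange(self.ny) * self.dy

    def z_slice_centers(self) -> np.ndarray:
        """z positions of the slice centers, ``(m + 1/2) dz``."""
        return (np.arange(self.nz) + 0.5) * self.dz

    def kx_grid(self) -> np.ndarray:
        """Angular spatial frequencies of the lateral FFT grid along x."""
        return 2.0 * np.pi * np.fft.fftfreq(self.nx, d=self.dx)

    def ky_grid(self) -> np.ndarray:
        return 2.0 * np.pi * np.fft.fftfreq(self.ny, d=self.dy)

    def transverse_k2(self) -> np.ndarray:
        """|k_t|² on the lateral FFT grid, shape ``(ny, nx)``."""
        kx = self.kx_grid()
        ky = self.ky_grid()
        return ky[:, None] ** 2 + kx[None, :] ** 2

    def with_nz(self, nz: int) -> "GridSpec":
        return dataclasses.replace(self, nz=nz)


@dataclasses.dataclass
class RIVolume:
    """A refractive-index map on a :class:`GridSpec`.

    ``n`` may be complex for absorbing samples; its real part must be >= 1.
    """

    grid: GridSpec
    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        if self.n.shape != self.grid.shape:
            raise ValueError(
                f"array shape {self.n.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.n)):
            raise ValueError("refractive index contains non-finite values")
        if np.min(self.n.real) < 1.0 - 1e-12:
            raise ValueError("real part of the refractive index must be >= 1")

    @property
    def delta_n(self) -> np.ndarray:
        """Index contrast δn = n − n_b."""
        return self.n - self.grid.n_b

    def copy(self) -> "RIVolume":
        return RIVolume(self.grid, self.n.copy())


def potential_from_ri(vol: RIVolume) -> np.ndarray:
    """Scattering potential ``V = k_b² [(n/n_b)² − 1]`` of a volume."""
    kb2 = vol.grid.kb**2
    return kb2 * ((vol.n / vol.grid.n_b) ** 2 - 1.0)


def ri_from_potential(V: np.ndarray, grid: GridSpec) -> RIVolume:
    """Invert :func:`potential_from_ri`: ``n = n_b sqrt(V/k_b² + 1)``.

    Raises
    ------
    ValueError
        If any real ``V < −k_b²``, which would produce an imaginary index.
    """
    V = np.asarray(V)
    kb2 = grid.kb**2
    arg = V / kb2 + 1.0
    if not np.iscomplexobj(arg) and np.min(arg) < 0:
        raise ValueError("potential below -k_b^2: no real refractive index")
    n = grid.n_b * np.sqrt(arg)
    return RIVolume(grid, n)
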