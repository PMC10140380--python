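"""Synthetic refractive-index phantoms.

The centerpiece is a multicellular-spheroid phantom: cells packed on a
body-centered cubic (BCC) lattice, each cell a sphere of cytoplasm
(n = 1.370) containing a concentric nucleus (n = 1.355), a nucleolus
(n = 1.370) inside the nucleus, and a handful of high-index vesicles
(n = 1.410), with the internal geometry of every cell randomly rotated.
Simpler phantoms (homogeneous spheres, vesicle-bath slabs) support the
propagation and reconstruction test batteries.

Voxelization rule: a voxel belongs to a sphere iff its *center* lies inside
the sphere.  No antialiasing — generation is pure and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .core import GridSpec, RIVolume

__all__ = [
    "SpheroidSpec",
    "make_homogeneous_sphere",
    "make_bcc_centers",
    "make_spheroid_phantom",
    "make_two_layer_phantom",
]


@dataclasses.dataclass(frozen=True)
class SpheroidSpec:
    """Geometry and optical parameters of the multicellular spheroid phantom.

    Lengths share the grid's unit (λ0 in simulation configs).  The nucleus,
    nucleolus and vesicle diameters are expressed as fractions of the cell
    diameter; their absolute values are free parameters of the phantom.
    """

    spheroid_diameter: float = 122.0
    cell_diameter: float = 14.0
    lattice_constant: float = 18.0
    n_cytoplasm: float = 1.370
    n_nucleus: float = 1.355
    n_nucleolus: float = 1.370
    n_vesicle: float = 1.410
    nucleus_fraction: float = 0.6
    nucleolus_fraction: float = 0.2
    vesicle_fraction: float = 0.1
    vesicle_count_per_cell: int = 5
    rotation_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_diameter >= self.spheroid_diameter:
            raise ValueError("cell diameter must be smaller than spheroid diameter")
        if self.lattice_constant <= 0:
            raise ValueError("lattice constant must be positive")


def _grid_center(grid: GridSpec) -> tuple[float, float, float]:
    """Geometric center of the grid (x, y, z)."""
    lx, ly, lz = grid.extent
    return (lx / 2.0, ly / 2.0, lz / 2.0)


def _paint_sphere(
    n: np.ndarray, grid: GridSpec, center: tuple[float, float, float],
    diameter: float, value: float,
) -> int:
    """Assign ``value`` to voxels whose center lies inside the sphere.

    Works on a bounding sub-box only.  Returns the number of voxels painted.
    """
    cx, cy, cz = center
    r = diameter / 2.0
    # voxel centers are at (i + 0.5) * pitch
    ix0 = max(int(np.floor((cx - r) / grid.dx - 0.5)), 0)
    ix1 = min(int(np.ceil((cx + r) / grid.dx - 0.5)) + 1, grid.nx)
    iy0 = max(int(np.floor((cy - r) / grid.dy - 0.5)), 0)
    iy1 = min(int(np.ceil((cy + r) / grid.dy - 0.5)) + 1, grid.ny)
    iz0 = max(int(np.floor((cz - r) / grid.dz - 0.5)), 0)
    iz1 = min(int(np.ceil((cz + r) / grid.dz - 0.5)) + 1, grid.nz)
    if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
        return 0
    x = (np.arange(ix0, ix1) + 0.5) * grid.dx - cx
    y = (np.arange(iy0, iy1) + 0.5) * grid.dy - cy
    z = (np.arange(iz0, iz1) + 0.5) * grid.dz - cz
    mask = (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
        <= r * r
    )
    n[iz0:iz1, iy0:iy1, ix0:ix1][mask] = value
    return int(mask.sum())


def make_homogeneous_sphere(
    grid: GridSpec, diameter: float, n_in: float
) -> RIVolume:
    """A homogeneous sphere of index ``n_in`` centered in the grid.

    Raises
    ------
    ValueError
        If the sphere does not fit inside the grid extent; the message names
        the first offending axis.
    """
    for axis, ext in zip("xyz", grid.extent):
        if diameter > ext + 1e-12:
            raise ValueError(
                f"sphere diameter {diameter} exceeds grid extent {ext} along {axis}"
            )
    n = np.full(grid.shape, grid.n_b, dtype=float)
    _paint_sphere(n, grid, _grid_center(grid), diameter, n_in)
    return RIVolume(grid, n)


def make_bcc_centers(
    spheroid_diameter: float, lattice_constant: float
) -> np.ndarray:
    """All BCC lattice sites inside a ball of the given diameter.

    The corner sublattice is anchored with one site exactly at the origin
    (the spheroid center); the body-center sublattice is offset by half the
    lattice constant along every axis.  A site is kept iff its Euclidean
    distance from the origin is at most ``spheroid_diameter / 2``.

    Returns an ``(n_sites, 3)`` array of (x, y, z) coordinates, sorted
    lexicographically for determinism.
    """
    if spheroid_diameter <= 0 or lattice_constant <= 0:
        raise ValueError("diameter and lattice constant must be positive")
    a = lattice_constant
    radius = spheroid_diameter / 2.0
    m = int(np.floor(radius / a)) + 1
    rng = np.arange(-m, m + 1, dtype=float)
    gx, gy, gz = np.meshgrid(rng, rng, rng, indexing="ij")
    corner = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) * a
    body = corner + a / 2.0
    sites = np.concatenate([corner, body], axis=0)
    keep = np.linalg.norm(sites, axis=1) <= radius + 1e-9 * a
    sites = sites[keep]
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
    return sites[order]


def make_spheroid_phantom(grid: GridSpec, spec: SpheroidSpec) -> RIVolume:
    """Voxelize the multicellular spheroid phantom onto ``grid``.

    Each cell's internal organelle layout is generated in a cell-local frame
    and rotated by a random rotation drawn from ``spec.rotation_seed``; the
    whole construction is deterministic for a fixed seed.  Later cells
    overwrite earlier ones where cells overlap (a single warning is issued).
    """
    for axis, ext in zip("xyz", grid.extent):
        if spec.spheroid_diameter > ext + 1e-12:
            raise ValueError(
                f"spheroid diameter {spec.spheroid_diameter} exceeds grid "
                f"extent {ext} along {axis}"
            )
    centers = make_bcc_centers(spec.spheroid_diameter, spec.lattice_constant)
    if len(centers) > 1:
        min_sep = spec.lattice_constant * np.sqrt(3.0) / 2.0
        if spec.cell_diameter > min_sep:
            warnings.warn(
                "cells overlap (cell diameter exceeds nearest-neighbor "
                "distance); later voxel assignment wins",
                stacklevel=2,
            )
    rng = np.random.default_rng(spec.rotation_seed)
    n = np.full(grid.shape, grid.n_b, dtype=float)
    origin = np.asarray(_grid_center(grid))

    d_cell = spec.cell_diameter
    d_nuc = spec.nucleus_fraction * d_cell
    d_nucleolus = spec.nucleolus_fraction * d_cell
    d_ves = spec.vesicle_fraction * d_cell

    for site in centers:
        rot = Rotation.random(rng=rng)
        c = origin + site
        _paint_sphere(n, grid, tuple(c), d_cell, spec.n_cytoplasm)
        _paint_sphere(n, grid, tuple(c), d_nuc, spec.n_nucleus)
        # nucleolus: random position strictly inside the nucleus
        r_max = max((d_nuc - d_nucleolus) / 2.0, 0.0)
        offset = rot.apply(_random_point_in_ball(rng, r_max))
        _paint_sphere(n, grid, tuple(c + offset), d_nucleolus, spec.n_nucleolus)
        # vesicles: uniform in the cytoplasmic shell (outside the nucleus,
        # inside the cell), so they never touch the nucleolus
        r_lo = d_nuc / 2.0 + d_ves / 2.0
        r_hi = d_cell / 2.0 - d_ves / 2.0
        if spec.vesicle_count_per_cell > 0 and r_hi <= r_lo:
            warnings.warn(
                "cytoplasmic shell too thin for the requested vesicle "
                "diameter; no vesicles placed",
                stacklevel=2,
            )
        for _ in range(spec.vesicle_count_per_cell):
            if r_hi <= r_lo:
                break
            offset = rot.apply(_random_point_in_shell(rng, r_lo, r_hi))
            _paint_sphere(n, grid, tuple(c + offset), d_ves, spec.n_vesicle)
    return RIVolume(grid, n)


def make_two_layer_phantom(
    grid: GridSpec,
    seed: int,
    n_vesicles: int = 60,
    vesicle_diameter: float = 2.0,
    n_vesicle: float = 1.410,
    n_test: float = 1.355,
    test_diameter: float = 3.0,
    n_test_spheres: int = 4,
) -> RIVolume:
    """A depth-evaluation phantom: a strongly scattering vesicle-rich layer
    on the detection side (upper half in z) above a weak test layer of a few
    moderate-contrast spheres near the illumination side.

    The vesicle layer emulates the multiple scattering and sample-induced
    aberration that corrupt the view of deeper structure; reconstruction
    quality of the test layer then discriminates clearing from no-clearing.
    Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = grid.extent
    n = np.full(grid.shape, grid.n_b, dtype=float)
    margin = vesicle_diameter / 2.0 + grid.dx
    # scattering layer: upper z (detection side), z in [0.55, 0.9]*lz
    for _ in range(n_vesicles):
        c = (
            rng.uniform(margin, lx - margin),
            rng.uniform(margin, ly - margin),
            rng.uniform(0.55 * lz, 0.90 * lz),
        )
        _paint_sphere(n, grid, c, vesicle_diameter, n_vesicle)
    # test layer: weak spheres at fixed depth near the illumination side
    z_test = 0.2 * lz
    for i in range(n_test_spheres):
        cx = lx * (0.28 + 0.44 * ((i % 2)))
        cy = ly * (0.28 + 0.44 * ((i // 2) % 2))
        _paint_sphere(n, grid, (cx, cy, z_test), test_diameter, n_test)
    return RIVolume(grid, n)


def _random_point_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius == 0.0:
        return np.zeros(3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return r * direction

def _random_point_in_shell(
    rng: np.random.Generator, r_lo: float, r_hi: float
) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    u = rng.uniform()
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    return r * direction
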