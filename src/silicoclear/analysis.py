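"""Downstream biological quantification of reconstructed tomograms.

Three analyses mirror the assays run on spheroid RI maps:

* morphology — spheroid volume as the integral of voxels above a foreground
  threshold (default n > 1.340), the equivalent spherical diameter, and the
  high-RI (lipid-like) volume ratio (default n > 1.375);
* fragmentation — apoptotic-body detection by a fourth-derivative-of-Gaussian
  spatial filter on the RI map, giving the non-fragmented volume ratio used
  as a viability proxy;
* dose–response — Hill-model fitting of effect vs. drug concentration,
  yielding the relative EC50 and Hill exponent.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .core import RIVolume

__all__ = [
    "MorphologyResult",
    "FragmentationResult",
    "HillFit",
    "spheroid_morphology",
    "fragmentation_map",
    "hill_curve",
    "fit_hill",
]


@dataclasses.dataclass(frozen=True)
class MorphologyResult:
    volume: float            # foreground volume, physical units³
    equivalent_diameter: float
    high_ri_ratio: float | None  # None when the foreground is empty
    threshold_foreground: float
    threshold_high: float


@dataclasses.dataclass
class FragmentationResult:
    foreground: np.ndarray
    fragmented: np.ndarray
    non_fragmented_ratio: float
    sigma: tuple[float, float, float]
    threshold: float


@dataclasses.dataclass(frozen=True)
class HillFit:
    E0: float
    E_inf: float
    EC50: float
    H: float
    residual_norm: float


def spheroid_morphology(
    vol: RIVolume, t_fg: float = 1.340, t_high: float = 1.375
) -> MorphologyResult:
    """Spheroid volume, equivalent diameter and high-RI volume ratio.

    ``V_sph`` integrates all voxels with n > ``t_fg``; the equivalent
    diameter assumes a spherical shape, d_eq = 2 (3 V_sph / 4π)^(1/3); the
    high-RI ratio divides the volume with n > ``t_high`` by ``V_sph``.
    """
    n = vol.n.real
    dv = vol.grid.voxel_volume
    fg = n > t_fg
    v_sph = float(fg.sum()) * dv
    if v_sph == 0.0:
        return MorphologyResult(0.0, 0.0, None, t_fg, t_high)
    v_high = float((n > t_high).sum()) * dv
    d_eq = 2.0 * (3.0 * v_sph / (4.0 * np.pi)) ** (1.0 / 3.0)
    return MorphologyResult(v_sph, d_eq, v_high / v_sph, t_fg, t_high)


def _gauss_kernel(sig: float, deriv4: bool) -> np.ndarray:
    """Sampled Gaussian (sum 1) or its fourth derivative (sum exactly 0)."""
    radius = max(int(np.ceil(6.0 * sig)), 2)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sig) ** 2)
    if not deriv4:
        return g / g.sum()
    t2 = (x / sig) ** 2
    k = (t2 * t2 - 6.0 * t2 + 3.0) / sig**4 * g
    return k - k.mean()  # enforce zero response to constants


def fragmentation_response(vol: RIVolume, sigma: tuple[float, float, float]) -> np.ndarray:
    """Magnitude of the fourth-derivative-of-Gaussian filter response.

    The filter is separable: for each axis the 1D fourth derivative of a
    Gaussian (that axis' σ) is combined with plain Gaussians along the other
    two axes; the three axis responses are summed and the magnitude taken.
    σ is given in physical units (σx, σy, σz) and converted to voxels.  The
    derivative kernels are normalized to zero sum, so a constant volume has
    an identically zero response.
    """
    n = vol.n.real.astype(float)
    g = vol.grid
    sig_vox = (sigma[2] / g.dz, sigma[1] / g.dy, sigma[0] / g.dx)  # (z, y, x)
    resp = np.zeros_like(n)
    for axis in range(3):
        out = n
        for ax2 in range(3):
            out = ndimage.correlate1d(
                out, _gauss_kernel(sig_vox[ax2], deriv4=(ax2 == axis)),
                axis=ax2, mode="reflect",
            )
        resp += out
    return np.abs(resp)


def fragmentation_map(
    vol: RIVolume,
    sigma: tuple[float, float, float] = (0.138, 0.138, 0.400),
    t_fg: float = 1.34,
    frag_threshold: float | None = None,
) -> FragmentationResult:
    """Fragmented-region extraction and the non-fragmented volume ratio.

    The fragmented region is the intersection of the foreground
    (n > ``t_fg``) with the super-threshold response of the
    fourth-derivative-of-Gaussian filter.  When ``frag_threshold`` is not
    given, Otsu's threshold of the response within the foreground is used.
    The default σ corresponds to (138 nm, 138 nm, 400 nm) on a µm grid.
    """
    if min(sigma) <= 0:
        raise ValueError("sigma must be positive per axis")
    n = vol.n.real
    fg = n > t_fg
    resp = fragmentation_response(vol, sigma)
    if not fg.any():
        return FragmentationResult(fg, np.zeros_like(fg), 1.0, tuple(sigma), np.inf)
    if frag_threshold is None:
        vals = resp[fg]
        if np.allclose(vals, vals.flat[0]):
            frag_threshold = np.inf  # constant response: nothing fragments
        else:
            frag_threshold = float(threshold_otsu(vals))
    fragmented = fg & (resp > frag_threshold)
    ratio = float((fg & ~fragmented).sum() / fg.sum())
    return FragmentationResult(fg, fragmented, ratio, tuple(sigma), frag_threshold)


def hill_curve(C, E0: float, E_inf: float, EC50: float, H: float):
    """E(C) = E0 + (E_inf − E0) / (1 + (EC50/C)^H), with E(0) = E0."""
    C = np.asarray(C, dtype=float)
    out = np.full(C.shape, E0, dtype=float)
    pos = C > 0
    out[pos] = E0 + (E_inf - E0) / (1.0 + (EC50 / C[pos]) ** H)
    return out


def fit_hill(
    concentrations: Sequence[float], effects: Sequence[float]
) -> HillFit:
    """Nonlinear least-squares Hill fit with bounds EC50 > 0, H > 0.

    Initialization is deterministic: E0 from the mean effect at the lowest
    concentration, E_inf from the highest, EC50 at the geometric
    mid-concentration, H = 1.  Zero concentrations contribute E0 to the
    residual (the C → 0 limit of the model for H > 0).
    """
    C = np.asarray(concentrations, dtype=float)
    E = np.asarray(effects, dtype=float)
    if C.shape != E.shape:
        raise ValueError("concentrations and effects must align")
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    if len(np.unique(C)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    c_lo, c_hi = C.min(), C.max()
    E0_init = float(E[C == c_lo].mean())
    Einf_init = float(E[C == c_hi].mean())
    pos = C[C > 0]
    ec50_init = float(np.sqrt(pos.min() * pos.max()))
    p0 = [E0_init, Einf_init, ec50_init, 1.0]

    def resid(p):
        return hill_curve(C, *p) - E

    tiny = 1e-12
    sol = optimize.least_squares(
        resid,
        p0,
        bounds=([-np.inf, -np.inf, tiny, tiny], [np.inf, np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"Hill fit did not converge: {sol.message}; last iterate {sol.x}"
        )
    E0, E_inf, ec50, h = sol.x
    return HillFit(float(E0), float(E_inf), float(ec50), float(h),
                   float(np.linalg.norm(sol.fun)))
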