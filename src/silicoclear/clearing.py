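"""The in-silico clearing loop, plus the no-clearing and conventional-Rytov
baselines.

The reconstruction volume is split along z into blocks of nominal length
``l_b``.  Starting from the block nearest the detection lens, the loop

1. digitally refocuses the current fields to the block's z-planes and
   computes the sheared QPGI stack there (free-space propagation — the
   block's own RI is unknown at that point);
2. reconstructs the block's partial RI slab from the stack (ADMM inversion
   of the calibrated QPGI kernel);
3. backpropagates the fields through the reconstructed slab with the
   multi-slice BPM, which strips the wavefront distortion (multiple
   scattering and sample-induced aberration) that the slab imprinted on
   them, and hands clean fields to the next block.

Repeating this until the illumination side of the sample and concatenating
the slabs yields the full tomogram.  Without clearing, one QPGI stack over
the whole extent is inverted in a single step; the conventional-Rytov
baseline maps per-angle Rytov phases onto Ewald shells (classical optical
diffraction tomography) and applies the same regularized inversion.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import fft as sfft
from skimage.restoration import unwrap_phase

from .core import GridSpec, RIVolume, ri_from_potential
from .fieldsynth import compute_qpgi_stack
from .recon import (
    QPGIKernel,
    QPGIOperator,
    ReconConfig,
    _cg,
    _grad,
    _grad_adjoint,
    _soft,
    admm_reconstruct,
    calibrate_qpgi_kernel,
)
from .wavesim import FieldSet, IlluminationSet, bpm_backpropagate

__all__ = [
    "BlockPlan",
    "split_blocks",
    "run_insilico_clearing",
    "run_without_clearing",
    "run_conventional_rytov",
]


@dataclasses.dataclass(frozen=True)
class BlockPlan:
    """Ordered z-slabs covering the reconstruction extent.

    ``blocks`` are half-open intervals [z_lo, z_hi) listed from the
    detection side (high z) to the illumination side (z = 0); they tile the
    extent without overlap or gap and none exceeds ``l_b``.
    """

    blocks: tuple[tuple[float, float], ...]
    l_b: float

    def __post_init__(self) -> None:
        zs = list(self.blocks)
        for (lo, hi) in zs:
            if hi <= lo:
                raise ValueError("empty block")
            if hi - lo > self.l_b * (1 + 1e-9):
                raise ValueError("block longer than l_b")
        for (lo0, _), (_, hi1) in zip(zs[:-1], zs[1:]):
            if abs(lo0 - hi1) > 1e-9:
                raise ValueError("blocks must tile without overlap or gap")

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def z_extent(self) -> float:
        return self.blocks[0][1] - self.blocks[-1][0]


def split_blocks(z_extent: float, l_b: float) -> BlockPlan:
    """Split ``z_extent`` into ``ceil(z_extent / l_b)`` blocks.

    The detection-side blocks take the nominal length; the final
    (illumination-side) block absorbs the remainder.
    """
    if z_extent <= 0 or l_b <= 0:
        raise ValueError("extent and block length must be positive")
    n = int(np.ceil(z_extent / l_b - 1e-9))
    blocks = []
    hi = z_extent
    for i in range(n):
        lo = 0.0 if i == n - 1 else max(hi - l_b, 0.0)
        blocks.append((lo, hi))
        hi = lo
    return BlockPlan(blocks=tuple(blocks), l_b=l_b)


def _block_slices(plan: BlockPlan, grid: GridSpec) -> list[tuple[int, int]]:
    """Voxel-slice index ranges [i_lo, i_hi) for each block, detection first."""
    edges = [b[0] for b in plan.blocks[::-1]] + [plan.blocks[0][1]]
    idx = [int(round(e / grid.dz)) for e in edges]
    if idx[0] != 0 or idx[-1] != grid.nz:
        raise ValueError("block plan does not span the volume z-extent")
    pairs = [(idx[i], idx[i + 1]) for i in range(len(idx) - 1)]
    for lo, hi in pairs:
        if hi <= lo:
            raise ValueError("block boundaries collapse onto the voxel grid")
    return pairs[::-1]


def _phase_flatness(fs: FieldSet) -> float:
    """Circular variance of the carrier-normalized phase, averaged over
    illuminations; 0 for perfectly flat wavefronts."""
    from .fieldsynth import normalize_field

    vals = []
    for f in fs:
        fn = normalize_field(f) if not f.carrier_removed else f
        ph = np.exp(1j * np.angle(fn.u))
        vals.append(1.0 - abs(ph.mean()))
    return float(np.mean(vals))


def run_insilico_clearing(
    fs: FieldSet,
    plan: BlockPlan,
    ills: IlluminationSet,
    cfg: ReconConfig | None = None,
    na_det: float = 1.0,
    shear_x: float | None = None,
    shear_y: float | None = None,
    kernel_mode: str = "calibrated",
    diagnostics: dict | None = None,
) -> RIVolume:
    """Block-wise partial reconstruction with wave-backpropagation.

    ``fs`` must sit at the detection-side boundary of the first block
    (propagate from the camera plane first if necessary).  Kernels are
    calibrated lazily per distinct block depth and freed with the loop;
    nothing 4D is ever held.  If a ``diagnostics`` dict is supplied it is
    filled with per-block phase-flatness values and objective traces.
    """
    grid = fs.grid
    pairs = _block_slices(plan, grid)
    nz_total = pairs[0][1] - pairs[-1][0]
    full = np.empty((nz_total, grid.ny, grid.nx))
    kernels: dict[int, QPGIKernel] = {}
    current = fs
    if diagnostics is not None:
        diagnostics.setdefault("blocks", [])
    for bi, (i_lo, i_hi) in enumerate(pairs):
        nz_b = i_hi - i_lo
        try:
            if nz_b not in kernels:
                kernels[nz_b] = calibrate_qpgi_kernel(
                    ills, grid, nz_block=nz_b, shear_x=shear_x,
                    shear_y=shear_y, na_det=na_det, mode=kernel_mode,
                )
            kern = kernels[nz_b]
            z_planes = (np.arange(i_lo, i_hi) + 0.5) * grid.dz
            stack = compute_qpgi_stack(
                current, z_planes, shear_x=kern.shear_x, shear_y=kern.shear_y
            )
            slab, trace = admm_reconstruct(stack, kern, cfg)
            full[i_lo:i_hi] = slab.n.real
            slab_grid = grid.with_nz(nz_b)
            slab_vol = RIVolume(slab_grid, slab.n)
            flat_before = _phase_flatness(current)
            shifted = FieldSet(
                [dataclasses.replace(f, z=nz_b * grid.dz) for f in current]
            )
            current = bpm_backpropagate(shifted, slab_vol)
            current = FieldSet(
                [dataclasses.replace(f, z=i_lo * grid.dz) for f in current]
            )
            flat_after = _phase_flatness(current)
            if diagnostics is not None:
                diagnostics["blocks"].append(
                    {
                        "index": bi,
                        "z_range": [i_lo * grid.dz, i_hi * grid.dz],
                        "phase_flatness_before": flat_before,
                        "phase_flatness_after": flat_after,
                        "objective_trace": [float(t) for t in trace],
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"in-silico clearing failed at block {bi}") from exc
    return RIVolume(grid.with_nz(nz_total), full)


def run_without_clearing(
    fs: FieldSet,
    ills: IlluminationSet,
    cfg: ReconConfig | None = None,
    na_det: float = 1.0,
    shear_x: float | None = None,
    shear_y: float | None = None,
    kernel_mode: str = "calibrated",
    diagnostics: dict | None = None,
) -> RIVolume:
    """Single QPGI stack over the full z-extent, single inversion — the
    multiple-scattering-suppressive Rytov baseline without backpropagation."""
    grid = fs.grid
    plan = split_blocks(grid.nz * grid.dz, grid.nz * grid.dz)
    return run_insilico_clearing(
        fs, plan, ills, cfg=cfg, na_det=na_det, shear_x=shear_x,
        shear_y=shear_y, kernel_mode=kernel_mode, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# conventional Rytov (classical optical diffraction tomography) baseline
# ---------------------------------------------------------------------------

class _FourierMaskOperator:
    """y = F x restricted to the filled Ewald-shell voxels (unitary FFT)."""

    def __init__(self, mask: np.ndarray):
        self.mask = mask
        self.shape_in = mask.shape

    def forward(self, x: np.ndarray):
        X = sfft.fftn(x, norm="ortho")
        return (np.where(self.mask, X, 0.0),)

    def adjoint(self, y: np.ndarray):
        return sfft.ifftn(np.where(self.mask, y, 0.0), norm="ortho").real


def run_conventional_rytov(
    fs: FieldSet,
    ills: IlluminationSet,
    cfg: ReconConfig | None = None,
    na_det: float = 1.0,
) -> RIVolume:
    """Classical ODT: per-angle Rytov complex phase, Fourier-diffraction
    mapping onto Ewald shells, then the same regularized (ℓ1 + TV,
    non-negative) inversion of the sampled spectrum.

    Phase unwrapping failures are flagged with a warning; the reconstruction
    is still returned (for strongly scattering samples this baseline is
    expected to fail — that failure is the point of the comparison).
    """
    if cfg is None:
        cfg = ReconConfig()
    grid = fs.grid
    z_d = fs.z
    kb2 = grid.kb**2
    kt2 = grid.transverse_k2()
    kzg = np.sqrt(np.maximum(kb2 - kt2, 0.0))
    det_ok = (kt2 <= (na_det * grid.k0) ** 2 * (1 + 1e-12)) & (kt2 < kb2)
    dkx = 2 * np.pi / (grid.nx * grid.dx)
    dky = 2 * np.pi / (grid.ny * grid.dy)
    dkz = 2 * np.pi / (grid.nz * grid.dz)
    x = grid.x_coords()
    y = grid.y_coords()
    vhat = np.zeros(grid.shape, dtype=complex)
    counts = np.zeros(grid.shape)
    unwrap_suspect = False
    iy, ix = np.nonzero(det_ok)
    kxf = grid.kx_grid()
    kyf = grid.ky_grid()
    kz_s = kzg[iy, ix]
    for f in fs:
        ill = f.illumination
        u_in = np.exp(
            1j * (ill.kx * x[None, :] + ill.ky * y[:, None] + ill.kz * z_d)
        )
        ratio = f.u / u_in
        amp = np.maximum(np.abs(ratio), 1e-6)
        phase = unwrap_phase(np.angle(ratio))
        if max(
            np.abs(np.diff(phase, axis=0)).max(),
            np.abs(np.diff(phase, axis=1)).max(),
        ) > 0.9 * np.pi:
            unwrap_suspect = True
        rytov = np.log(amp) + 1j * phase
        s_hat = sfft.fft2(u_in * rytov) * (grid.dx * grid.dy)
        # scattered spectrum -> potential samples on the Ewald shell
        Kx = kxf[ix] - ill.kx
        Ky = kyf[iy] - ill.ky
        Kz = kz_s - ill.kz
        bz = np.rint(Kz / dkz).astype(int)
        bx = np.rint(Kx / dkx).astype(int)
        by = np.rint(Ky / dky).astype(int)
        ok = (bz > -grid.nz // 2) & (bz <= grid.nz // 2)
        # the BPM measurement registers slice iz at plane (iz+1)*dz, hence
        # the extra e^{+i Kz dz} registration factor
        val = (
            -2j * kz_s * np.exp(-1j * kz_s * z_d) * s_hat[iy, ix]
            * np.exp(1j * Kz * grid.dz)
        )
        # nearest-bin rounding: re-reference the rounding phase error to the
        # grid center so a centered object is not incoherently attenuated
        xc, yc, zc = (
            grid.nx // 2 * grid.dx,
            grid.ny // 2 * grid.dy,
            grid.nz // 2 * grid.dz,
        )
        val = val * np.exp(
            1j
            * (
                (Kx - bx * dkx) * xc
                + (Ky - by * dky) * yc
                + (Kz - bz * dkz) * zc
            )
        )
        flat = (
            (bz[ok] % grid.nz) * grid.ny * grid.nx
            + (by[ok] % grid.ny) * grid.nx
            + (bx[ok] % grid.nx)
        )
        np.add.at(vhat.ravel(), flat, val[ok])
        np.add.at(counts.ravel(), flat, 1.0)
    if unwrap_suspect:
        warnings.warn(
            "Rytov phase unwrapping is suspect (residual jumps near pi); "
            "reconstruction returned anyway", stacklevel=2,
        )
    filled = counts > 0
    vhat[filled] /= counts[filled]
    # Hermitian-symmetrize (V is real)
    conj_idx = tuple(
        (-np.arange(s)) % s for s in grid.shape
    )
    vhat_conj = np.conj(
        vhat[np.ix_(*conj_idx)]
    )
    filled_conj = filled[np.ix_(*conj_idx)]
    both = filled & filled_conj
    only_conj = filled_conj & ~filled
    vhat[both] = 0.5 * (vhat[both] + vhat_conj[both])
    vhat[only_conj] = vhat_conj[only_conj]
    mask = filled | filled_conj
    # continuous FT -> discrete (ortho-normalized) spectrum of the potential
    y_data = (vhat / grid.voxel_volume) / np.sqrt(np.prod(grid.shape))
    op = _FourierMaskOperator(mask)
    V = _admm_generic(op, (np.where(mask, y_data, 0.0),), cfg)
    return ri_from_potential(np.maximum(V, 0.0), grid)


def _admm_generic(op, data, cfg: ReconConfig):
    """Same ADMM splitting as the QPGI inversion for a generic linear op."""
    rho = cfg.rho

    def atb():
        return op.adjoint(*data)

    x = np.zeros(op.shape_in)
    z1 = x.copy()
    u1 = np.zeros_like(x)
    z2 = _grad(x)
    u2 = np.zeros_like(z2)
    Atb = atb()

    def normal_op(v):
        fwd = op.forward(v)
        return op.adjoint(*fwd) + rho * v + rho * _grad_adjoint(_grad(v))

    for _ in range(cfg.iterations):
        rhs = Atb + rho * (z1 - u1) + rho * _grad_adjoint(z2 - u2)
        x = _cg(normal_op, rhs, x, cfg.cg_iterations, cfg.cg_tol)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("ADMM iterate contains non-finite values")
        z1 = _soft(x + u1, cfg.tau / rho)
        if cfg.nonneg:
            z1 = np.maximum(z1, 0.0)
        gx = _grad(x)
        z2 = _soft(gx + u2, cfg.xi / rho)
        u1 = u1 + x - z1
        u2 = u2 + gx - z2
    return z1
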