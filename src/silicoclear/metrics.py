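"""Volume image-quality metrics and the layer-wise depth evaluation.

NRE  = ‖n_recon − n_exact‖² / ‖n_exact‖²            (squared L2 norms)
PSNR = 10 log10( L² / MSE ),  L = max(n_exact) − min(n_exact)
SSIM = mean local structural similarity, C1 = (0.01 L)², C2 = (0.03 L)²,
       statistics in a uniform 7×7×7 sliding window.

For depth-resolved evaluation the volumes are partitioned into z-layers of a
fixed thickness (the last layer may be thinner) and every metric is computed
per layer with the dynamic range L taken from that layer of the ground
truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .core import RIVolume

__all__ = ["nre", "psnr", "ssim", "layerwise_metrics"]

SSIM_WINDOW = 7


def _as_arrays(recon, truth) -> tuple[np.ndarray, np.ndarray]:
    a = recon.n.real if isinstance(recon, RIVolume) else np.asarray(recon)
    b = truth.n.real if isinstance(truth, RIVolume) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    return a, b


def nre(recon, truth) -> float:
    """Normalized reconstruction error (0 for a perfect reconstruction)."""
    a, b = _as_arrays(recon, truth)
    denom = float(np.sum(b**2))
    if denom == 0.0:
        raise ValueError("ground truth is identically zero")
    return float(np.sum((a - b) ** 2) / denom)


def psnr(recon, truth) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the volumes coincide."""
    a, b = _as_arrays(recon, truth)
    L = float(b.max() - b.min())
    if L <= 0.0:
        raise ValueError("ground truth has zero dynamic range")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(L**2 / mse))


def ssim(recon, truth) -> float:
    """Mean structural similarity with the uniform 7×7×7 window.

    The dynamic range is taken from the ground truth; windows that do not
    fit entirely inside the volume are excluded (valid-mode borders).
    """
    a, b = _as_arrays(recon, truth)
    if min(a.shape) < SSIM_WINDOW:
        raise ValueError(f"volume smaller than the {SSIM_WINDOW}^3 window")
    L = float(b.max() - b.min())
    if L <= 0.0:
        raise ValueError("ground truth has zero dynamic range")
    return float(
        structural_similarity(
            b, a,
            win_size=SSIM_WINDOW,
            data_range=L,
            gaussian_weights=False,
            K1=0.01,
            K2=0.03,
        )
    )


def layerwise_metrics(
    recon: RIVolume, truth: RIVolume, layer_thickness: float
) -> pd.DataFrame:
    """Depth-resolved metric table.

    Volumes are split into tiled z-layers of ``layer_thickness`` starting at
    the illumination side (z = 0); the returned frame has one row per layer
    (``layer_center_z``, ``nre``, ``psnr_db``, ``ssim``) plus the global
    metrics stored in ``frame.attrs["global"]``.  Metrics undefined for a
    layer (constant truth, layer thinner than the SSIM window) are NaN.
    """
    if layer_thickness <= 0:
        raise ValueError("layer thickness must be positive")
    a, b = _as_arrays(recon, truth)
    grid = truth.grid
    per = max(int(round(layer_thickness / grid.dz)), 1)

    def safe(fn, ra, rb):
        try:
            return fn(ra, rb)
        except ValueError:
            return float("nan")

    rows = []
    for lo in range(0, grid.nz, per):
        hi = min(lo + per, grid.nz)
        ra, rb = a[lo:hi], b[lo:hi]
        rows.append({
            "layer_center_z": (lo + hi) / 2.0 * grid.dz,
            "nre": nre(ra, rb),
            "psnr_db": safe(psnr, ra, rb),
            "ssim": safe(ssim, ra, rb),
        })
    frame = pd.DataFrame(rows)
    frame.attrs["global"] = {
        "nre": nre(a, b),
        "psnr_db": safe(psnr, a, b),
        "ssim": safe(ssim, a, b),
    }
    return frame
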