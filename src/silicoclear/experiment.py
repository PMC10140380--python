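"""Seeded end-to-end experiment runner.

``run_experiment`` executes the full protocol — phantom generation, forward
BPM simulation of the angle-scanned measurement, reconstruction with and
without in-silico clearing (optionally also the conventional-Rytov
baseline), and layer-wise evaluation — and writes every artifact plus the
resolved configuration and provenance into a directory, fully deterministic
for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .clearing import (
    run_conventional_rytov,
    run_insilico_clearing,
    run_without_clearing,
    split_blocks,
)
from .config import ExperimentConfig, dumps_toml, save_config
from .core import RIVolume
from .metrics import layerwise_metrics
from .phantom import (
    SpheroidSpec,
    make_homogeneous_sphere,
    make_spheroid_phantom,
    make_two_layer_phantom,
)
from .storage import write_fieldset, write_volume
from .wavesim import make_illumination_grid, simulate_fieldset

__all__ = ["build_phantom", "run_experiment"]

log = logging.getLogger("silicoclear")


def build_phantom(cfg: ExperimentConfig) -> RIVolume:
    """Construct the phantom named by ``cfg.phantom_kind``."""
    g = cfg.grid
    p = dict(cfg.phantom)
    if cfg.phantom_kind == "empty":
        return RIVolume(g, np.full(g.shape, g.n_b))
    if cfg.phantom_kind == "sphere":
        return make_homogeneous_sphere(
            g, p.get("diameter", 4.0), p.get("n_in", g.n_b + 0.002)
        )
    if cfg.phantom_kind == "spheroid":
        p.setdefault("rotation_seed", cfg.seed)
        return make_spheroid_phantom(g, SpheroidSpec(**p))
    if cfg.phantom_kind == "two_layer":
        p.setdefault("seed", cfg.seed)
        return make_two_layer_phantom(g, **p)
    raise ValueError(f"unknown phantom kind {cfg.phantom_kind!r}")


def run_experiment(cfg: ExperimentConfig, outdir: str | Path) -> Path:
    """Run the full protocol into ``outdir`` and return that path.

    Artifacts: ``config.toml`` (resolved), ``truth.h5``, ``fields.h5``,
    ``recon_clearing.h5``, ``recon_noclearing.h5`` (and ``recon_rytov.h5``
    if requested), per-method ``metrics_*.csv``, ``diagnostics.json`` and
    ``provenance.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    timings: dict[str, float] = {}
    diagnostics: dict = {}
    try:
        save_config(cfg, outdir / "config.toml")
        g = cfg.grid

        stage = "phantom"
        t0 = time.perf_counter()
        truth = build_phantom(cfg)
        write_volume(truth, outdir / "truth.h5")
        timings[stage] = time.perf_counter() - t0

        stage = "simulate"
        t0 = time.perf_counter()
        ills = make_illumination_grid(
            cfg.na_ill, cfg.na_ill * g.k0 / cfg.illumination_spacing_factor, g
        )
        fs = simulate_fieldset(truth, ills, na_det=cfg.na_det)
        write_fieldset(fs, outdir / "fields.h5", na_det=cfg.na_det)
        timings[stage] = time.perf_counter() - t0
        log.info("simulated %d illuminations", len(ills))

        results: dict[str, RIVolume] = {}
        stage = "reconstruct-clearing"
        t0 = time.perf_counter()
        plan = split_blocks(g.nz * g.dz, cfg.block_length)
        diag_clear: dict = {}
        results["clearing"] = run_insilico_clearing(
            fs, plan, ills, cfg=cfg.recon, na_det=cfg.na_det,
            shear_x=cfg.shear_x, shear_y=cfg.shear_y, diagnostics=diag_clear,
        )
        diagnostics["clearing"] = diag_clear
        timings[stage] = time.perf_counter() - t0

        stage = "reconstruct-noclearing"
        t0 = time.perf_counter()
        results["noclearing"] = run_without_clearing(
            fs, ills, cfg=cfg.recon, na_det=cfg.na_det,
            shear_x=cfg.shear_x, shear_y=cfg.shear_y,
        )
        timings[stage] = time.perf_counter() - t0

        if cfg.run_rytov:
            stage = "reconstruct-rytov"
            t0 = time.perf_counter()
            results["rytov"] = run_conventional_rytov(
                fs, ills, cfg=cfg.recon, na_det=cfg.na_det
            )
            timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        for name, vol in results.items():
            write_volume(vol, outdir / f"recon_{name}.h5")
            frame = layerwise_metrics(vol, truth, cfg.layer_thickness)
            frame.to_csv(outdir / f"metrics_{name}.csv", index=False)
            diagnostics.setdefault("global_metrics", {})[name] = {
                k: (v if np.isfinite(v) else None)
                for k, v in frame.attrs["global"].items()
            }

        stage = "provenance"
        cfg_text = dumps_toml(cfg.to_dict())
        provenance = {
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "seed": cfg.seed,
            "version": __version__,
            "n_illuminations": len(ills),
            "timings_s": timings,
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
        (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}") from exc
    return outdir
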