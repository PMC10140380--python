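"""Experiment configuration: a TOML-serializable description of a full
phantom → simulate → reconstruct → evaluate run.

Seeds are mandatory — there are no entropy defaults anywhere in the
pipeline, so a stored config reproduces its run bit for bit.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .core import GridSpec
from .phantom import SpheroidSpec
from .recon import ReconConfig

__all__ = ["ExperimentConfig", "load_config", "save_config", "dumps_toml"]


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulated imaging experiment."""

    grid: GridSpec
    seed: int
    phantom_kind: str = "spheroid"           # spheroid | sphere | empty | two_layer
    phantom: dict = dataclasses.field(default_factory=dict)
    na_ill: float = 1.0
    na_det: float = 1.0
    illumination_spacing_factor: float = 3.5  # spacing = NA·k0 / factor
    block_length: float = 20.0
    layer_thickness: float = 18.0
    recon: ReconConfig = dataclasses.field(default_factory=ReconConfig)
    shear_x: float | None = None
    shear_y: float | None = None
    run_rytov: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "grid": dataclasses.asdict(self.grid),
            "seed": self.seed,
            "phantom_kind": self.phantom_kind,
            "phantom": dict(self.phantom),
            "acquisition": {
                "na_ill": self.na_ill,
                "na_det": self.na_det,
                "illumination_spacing_factor": self.illumination_spacing_factor,
            },
            "reconstruction": {
                **dataclasses.asdict(self.recon),
                "block_length": self.block_length,
                "shear_x": self.shear_x if self.shear_x is not None else 0.0,
                "shear_y": self.shear_y if self.shear_y is not None else 0.0,
                "run_rytov": self.run_rytov,
            },
            "evaluation": {"layer_thickness": self.layer_thickness},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        acq = d.get("acquisition", {})
        rec = dict(d.get("reconstruction", {}))
        block_length = rec.pop("block_length", 20.0)
        shear_x = rec.pop("shear_x", 0.0) or None
        shear_y = rec.pop("shear_y", 0.0) or None
        run_rytov = rec.pop("run_rytov", False)
        return cls(
            grid=GridSpec(**d["grid"]),
            seed=int(d["seed"]),
            phantom_kind=d.get("phantom_kind", "spheroid"),
            phantom=dict(d.get("phantom", {})),
            na_ill=float(acq.get("na_ill", 1.0)),
            na_det=float(acq.get("na_det", 1.0)),
            illumination_spacing_factor=float(
                acq.get("illumination_spacing_factor", 3.5)
            ),
            block_length=float(block_length),
            layer_thickness=float(d.get("evaluation", {}).get("layer_thickness", 18.0)),
            recon=ReconConfig(**rec) if rec else ReconConfig(),
            shear_x=shear_x,
            shear_y=shear_y,
            run_rytov=bool(run_rytov),
        )


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_toml(d: dict, prefix: str = "") -> str:
    """Minimal TOML emitter for nested dicts of scalars and lists."""
    scalars = {k: v for k, v in d.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in d.items() if isinstance(v, dict)}
    out = []
    for k, v in scalars.items():
        out.append(f"{k} = {_toml_value(v)}")
    for k, v in tables.items():
        name = f"{prefix}{k}"
        out.append(f"\n[{name}]")
        out.append(dumps_toml(v, prefix=name + "."))
    return "\n".join(out)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(dumps_toml(cfg.to_dict()) + "\n")


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path, "rb") as fh:
        return ExperimentConfig.from_dict(tomllib.load(fh))
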