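"""File formats: RI volumes (HDF5, multi-page TIFF), field sets and QPGI
stacks (HDF5).

HDF5 volumes hold the index array in ``/ri`` with the full grid description
as attributes; TIFF volumes are 32-bit float, one page per z-slice, with the
grid description serialized as JSON into the image description tag.  Reads
fail loudly when metadata is missing — no silent defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import GridSpec, RIVolume
from .fieldsynth import QPGIStack
from .wavesim import ComplexField, FieldSet, Illumination

__all__ = [
    "write_volume",
    "read_volume",
    "write_fieldset",
    "read_fieldset",
    "write_qpgi_stack",
    "read_qpgi_stack",
]

_GRID_ATTRS = ("nx", "ny", "nz", "dx", "dy", "dz", "wavelength", "n_b")


def _grid_to_dict(grid: GridSpec) -> dict:
    return {k: getattr(grid, k) for k in _GRID_ATTRS}


def _grid_from_dict(d: dict, source: str) -> GridSpec:
    missing = [k for k in _GRID_ATTRS if k not in d]
    if missing:
        raise ValueError(f"{source} lacks grid metadata: {', '.join(missing)}")
    return GridSpec(
        nx=int(d["nx"]), ny=int(d["ny"]), nz=int(d["nz"]),
        dx=float(d["dx"]), dy=float(d["dy"]), dz=float(d["dz"]),
        wavelength=float(d["wavelength"]), n_b=float(d["n_b"]),
    )


def write_volume(vol: RIVolume, path: str | Path) -> None:
    """Write an RI volume; format chosen by suffix (.h5/.hdf5 or .tif(f))."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("ri", data=vol.n)
            for k, v in _grid_to_dict(vol.grid).items():
                ds.attrs[k] = v
    elif path.suffix in (".tif", ".tiff"):
        if np.iscomplexobj(vol.n):
            raise ValueError("TIFF export supports real-valued volumes only")
        tifffile.imwrite(
            path,
            vol.n.astype(np.float32),
            photometric="minisblack",
            description=json.dumps(_grid_to_dict(vol.grid)),
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path: str | Path) -> RIVolume:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "ri" not in fh:
                raise ValueError(f"{path} has no /ri dataset")
            ds = fh["ri"]
            grid = _grid_from_dict(dict(ds.attrs), str(path))
            return RIVolume(grid, ds[()])
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
            try:
                meta = json.loads(desc) if desc else {}
            except json.JSONDecodeError:
                meta = {}
            grid = _grid_from_dict(meta, str(path))
            return RIVolume(grid, tf.asarray().astype(float))
    raise ValueError(f"unsupported volume format: {path.suffix}")


def write_fieldset(fs: FieldSet, path: str | Path, na_det: float | None = None) -> None:
    """Store a field set: ``/fields`` [N_in, ny, nx] complex, ``/k_in``
    [N_in, 3], grid and plane attributes at the root."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("fields", data=np.stack([f.u for f in fs]))
        fh.create_dataset("k_in", data=np.array(
            [[f.illumination.kx, f.illumination.ky, f.illumination.kz] for f in fs]
        ))
        for k, v in _grid_to_dict(fs.grid).items():
            fh.attrs[k] = v
        fh.attrs["z"] = fs.z
        if na_det is not None:
            fh.attrs["NA_det"] = na_det


def read_fieldset(path: str | Path) -> FieldSet:
    with h5py.File(path, "r") as fh:
        grid = _grid_from_dict(dict(fh.attrs), str(path))
        if "z" not in fh.attrs:
            raise ValueError(f"{path} lacks grid metadata: z")
        z = float(fh.attrs["z"])
        u = fh["fields"][()]
        k_in = fh["k_in"][()]
    fields = [
        ComplexField(
            u[j], z=z, grid=grid,
            illumination=Illumination(
                kx=float(k_in[j, 0]), ky=float(k_in[j, 1]),
                kz=float(k_in[j, 2]), index=j,
            ),
        )
        for j in range(len(u))
    ]
    return FieldSet(fields)


def write_qpgi_stack(stack: QPGIStack, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("psi_x", data=stack.psi_x)
        fh.create_dataset("psi_y", data=stack.psi_y)
        fh.attrs["shear_x"] = stack.shear_x
        fh.attrs["shear_y"] = stack.shear_y
        fh.create_dataset("z_planes", data=stack.z_planes)


def read_qpgi_stack(path: str | Path) -> QPGIStack:
    with h5py.File(path, "r") as fh:
        return QPGIStack(
            psi_x=fh["psi_x"][()],
            psi_y=fh["psi_y"][()],
            shear_x=float(fh.attrs["shear_x"]),
            shear_y=float(fh.attrs["shear_y"]),
            z_planes=fh["z_planes"][()],
        )
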