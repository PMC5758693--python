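"""File I/O: NIfTI volumes, HDF5 complex fields, JSON sidecars.

Conventions: NIfTI affines carry the voxel spacing in millimeters; complex
displacement fields live in a single HDF5 container with separate real and
imaginary datasets plus grid metadata; material palettes travel as JSON
sidecars next to the integer label volume.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .forward import HarmonicField
from .inversion import Elastogram
from .phantom import MaterialMap, VoxelGrid
from .rheology import ZenerParams

__all__ = [
    "save_material_map",
    "load_material_map",
    "save_field",
    "load_field",
    "save_elastogram",
    "save_phase_stack",
    "load_phase_stack",
]


def _affine(spacing_m: float) -> np.ndarray:
    mm = spacing_m * 1e3
    return np.diag([mm, mm, mm, 1.0])


def save_material_map(mmap: MaterialMap, labels_path, palette_path) -> None:
    """Write the label volume as NIfTI (spacing in mm) plus a JSON palette."""
    img = nib.Nifti1Image(
        mmap.labels.astype(np.int16), _affine(mmap.grid.spacing)
    )
    nib.save(img, str(labels_path))
    palette = {str(k): asdict(v) for k, v in mmap.palette.items()}
    Path(palette_path).write_text(json.dumps(palette, indent=2))


def load_material_map(labels_path, palette_path) -> MaterialMap:
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    spacing = float(img.header.get_zooms()[0]) * 1e-3
    palette = {
        int(k): ZenerParams(**v)
        for k, v in json.loads(Path(palette_path).read_text()).items()
    }
    grid = VoxelGrid(shape=labels.shape, spacing=spacing)
    return MaterialMap(grid=grid, labels=labels, palette=palette)


def save_field(field: HarmonicField, path) -> None:
    """Write a complex displacement field to one HDF5 container."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("real", data=field.values.real, compression="gzip")
        f.create_dataset("imag", data=field.values.imag, compression="gzip")
        f.attrs["spacing_m"] = field.grid.spacing
        f.attrs["origin_m"] = field.grid.origin
        f.attrs["frequency_hz"] = field.frequency
        f.attrs["units"] = "m"


def load_field(path) -> HarmonicField:
    with h5py.File(str(path), "r") as f:
        values = f["real"][()] + 1j * f["imag"][()]
        spacing = float(f.attrs["spacing_m"])
        origin = tuple(float(v) for v in f.attrs["origin_m"])
        frequency = float(f.attrs["frequency_hz"])
    grid = VoxelGrid(
        shape=tuple(n - 1 for n in values.shape[:3]), spacing=spacing, origin=origin
    )
    return HarmonicField(grid=grid, values=values, frequency=frequency)


def save_elastogram(elast: Elastogram, prefix) -> dict:
    """Write storage/loss (Pa) and validity-mask NIfTI volumes.

    Returns the mapping of written paths.  2-D (single-slice) elastograms are
    written as one-slice volumes.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(elast.grid.spacing)

    def vol(a: np.ndarray) -> np.ndarray:
        return a[..., None] if a.ndim == 2 else a

    paths = {}
    for name, data in (
        ("storage", vol(elast.storage).astype(np.float32)),
        ("loss", vol(elast.loss).astype(np.float32)),
        ("mask", vol(elast.valid_mask).astype(np.uint8)),
    ):
        p = prefix.parent / f"{prefix.name}_{name}.nii"
        nib.save(nib.Nifti1Image(data, aff), str(p))
        paths[name] = str(p)
    return paths


def save_phase_stack(phases, offsets, path) -> None:
    """Write a set of phase images (rad) at known motion offsets to HDF5."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset(
            "phase", data=np.stack([p.values for p in phases]), compression="gzip"
        )
        f.attrs["offsets_rad"] = np.asarray(offsets, dtype=float)
        f.attrs["spacing_m"] = phases[0].grid.spacing
        f.attrs["units"] = "rad"


def load_phase_stack(path):
    from .meg import PhaseImage

    with h5py.File(str(path), "r") as f:
        stack = f["phase"][()]
        offsets = [float(v) for v in f.attrs["offsets_rad"]]
        spacing = float(f.attrs["spacing_m"])
    grid = VoxelGrid(shape=tuple(n - 1 for n in stack.shape[1:4]), spacing=spacing)
    phases = [PhaseImage(grid=grid, values=v) for v in stack]
    return phases, offsets
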