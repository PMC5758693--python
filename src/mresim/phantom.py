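"""Voxelized tissue phantoms and excitation boundary conditions.

The reference geometry is a rectangular gel block (the full-size experiment
uses 100 x 70 x 55 mm at 1.25 mm cubic elements) with

* the bottom face (z = 0, an x-y slice) fully fixed,
* a circular patch (default 8 mm diameter) centered on the x = 0 face driven
  harmonically in the x direction at a prescribed complex amplitude,
* every other boundary node traction-free.

Heterogeneous variants embed a circular cylinder (axis along z, spanning the
full depth) of a stiffer material in the block.  All generation is
deterministic: identical inputs produce bit-identical label volumes.

Coordinates: node (0, 0, 0) sits at the phantom corner (the configurable
``origin``); x runs along the longest edge, z along the depth.  Element
``(i, j, k)`` occupies ``[i*h, (i+1)*h] x ... `` with spacing ``h``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .rheology import ZenerParams, complex_shear_modulus

__all__ = [
    "VoxelGrid",
    "MaterialMap",
    "BoundarySpec",
    "make_block_phantom",
    "add_cylindrical_inclusion",
    "make_boundary",
    "resolution_check",
    "shear_wavelength",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Structured grid of cubic elements.

    ``shape`` counts elements per axis; nodes number ``shape + 1`` per axis.
    ``spacing`` is the isotropic element edge length in meters.
    """

    shape: Tuple[int, int, int]
    spacing: float
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three counts >= 1, got {self.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def node_shape(self) -> Tuple[int, int, int]:
        return tuple(n + 1 for n in self.shape)

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical edge lengths, m."""
        return tuple(n * self.spacing for n in self.shape)

    def node_coords(self, axis: int) -> np.ndarray:
        """Physical node coordinates along one axis, m."""
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis] + 1)

    def element_centers(self, axis: int) -> np.ndarray:
        """Physical element-centroid coordinates along one axis, m."""
        return self.origin[axis] + self.spacing * (np.arange(self.shape[axis]) + 0.5)


@dataclass(frozen=True)
class MaterialMap:
    """Per-element material labels over a grid plus the label palette."""

    grid: VoxelGrid
    labels: np.ndarray
    palette: Dict[int, ZenerParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {labels.shape} does not match grid {self.grid.shape}"
            )
        if not self.palette:
            raise ValueError("palette must not be empty")
        present = set(np.unique(labels).tolist())
        missing = present - set(self.palette)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from palette")
        object.__setattr__(self, "labels", labels.astype(np.int16, copy=False))

    @property
    def present_labels(self) -> Tuple[int, ...]:
        return tuple(int(v) for v in np.unique(self.labels))

    def params_of(self, label: int) -> ZenerParams:
        return self.palette[int(label)]


@dataclass(frozen=True)
class BoundarySpec:
    """Dirichlet boundary data for one harmonic excitation.

    ``fixed_nodes`` and ``driven_nodes`` hold flat node indices (C order over
    the node grid).  Driven nodes are prescribed ``drive_vector`` on the
    components flagged by ``drive_components``; fixed nodes are clamped on all
    components.  Every other node is traction-free (unconstrained).
    """

    fixed_nodes: np.ndarray
    driven_nodes: np.ndarray
    drive_vector: np.ndarray
    frequency: float
    drive_components: Tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        fixed = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        driven = np.unique(np.asarray(self.driven_nodes, dtype=np.int64))
        if np.intersect1d(fixed, driven).size:
            raise ValueError("fixed and driven node sets must be disjoint")
        drive = np.asarray(self.drive_vector, dtype=np.complex128)
        if drive.shape != (3,):
            raise ValueError("drive_vector must be a complex 3-vector")
        if driven.size and not np.all(np.isfinite(drive.view(float))):
            raise ValueError("drive_vector must be finite")
        if driven.size and np.linalg.norm(drive[list(self.drive_components)]) == 0:
            raise ValueError("drive amplitude must be nonzero on the driven set")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        object.__setattr__(self, "fixed_nodes", fixed)
        object.__setattr__(self, "driven_nodes", driven)
        object.__setattr__(self, "drive_vector", drive)


def _element_counts(dims, spacing: float, rel_tol: float = 1e-9):
    counts = []
    for L in dims:
        n = L / spacing
        n_round = round(n)
        if n_round < 1 or abs(n - n_round) > rel_tol * max(abs(n), 1.0):
            lo = max(1, int(np.floor(n))) * spacing
            hi = int(np.ceil(n)) * spacing
            raise ValueError(
                f"dimension {L} m is not an integer multiple of spacing "
                f"{spacing} m; nearest valid sizes are {lo:.6g} m and {hi:.6g} m"
            )
        counts.append(int(n_round))
    return tuple(counts)


def make_block_phantom(
    dims: Tuple[float, float, float],
    spacing: float,
    params: ZenerParams,
    label: int = 0,
) -> MaterialMap:
    """Uniform single-material block of physical size ``dims`` (m).

    Each dimension must be a multiple of ``spacing`` (relative tolerance
    1e-9); otherwise the error lists the nearest commensurate sizes.
    """
    shape = _element_counts(dims, spacing)
    grid = VoxelGrid(shape=shape, spacing=spacing)
    labels = np.full(shape, label, dtype=np.int16)
    return MaterialMap(grid=grid, labels=labels, palette={int(label): params})


def add_cylindrical_inclusion(
    mmap: MaterialMap,
    center_xy: Tuple[float, float],
    diameter: float,
    params: ZenerParams,
    label: int | None = None,
) -> MaterialMap:
    """Embed a z-spanning circular cylinder of a second material.

    An element belongs to the cylinder when its centroid lies within
    ``diameter / 2`` of the axis (centroid rule, deterministic on the grid).
    The cylinder must fit inside the block footprint.
    """
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    grid = mmap.grid
    cx, cy = center_xy
    r = diameter / 2.0
    Lx, Ly, _ = grid.extent
    ox, oy = grid.origin[0], grid.origin[1]
    if cx - r < ox or cx + r > ox + Lx or cy - r < oy or cy + r > oy + Ly:
        raise ValueError(
            f"cylinder (center ({cx}, {cy}) m, diameter {diameter} m) extends "
            f"outside the block footprint {Lx} x {Ly} m"
        )
    if label is None:
        label = max(mmap.palette) + 1
    xs = grid.element_centers(0)
    ys = grid.element_centers(1)
    inside = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r**2
    labels = mmap.labels.copy()
    labels[inside, :] = label
    n_relabeled = int(inside.sum()) * grid.shape[2]
    if n_relabeled == 0:
        warnings.warn(
            "cylindrical inclusion captured no element centroids "
            f"(diameter {diameter} m vs spacing {grid.spacing} m)",
            stacklevel=2,
        )
    palette = dict(mmap.palette)
    palette[int(label)] = params
    return MaterialMap(grid=grid, labels=labels, palette=palette)


def make_boundary(
    mmap: MaterialMap,
    patch_center: Tuple[float, float] | None,
    patch_diameter: float,
    amplitude: complex,
    frequency: float,
) -> BoundarySpec:
    """Fixed bottom face plus a driven circular patch on the x = 0 face.

    ``patch_center`` is the (y, z) location of the patch on the x = 0 face
    (defaults to the face center).  Driven nodes are prescribed the complex
    displacement ``(amplitude, 0, 0)`` — in-line with the x axis, matching an
    indenter pushed normally onto that face.
    """
    if not patch_diameter > 0:
        raise ValueError("patch_diameter must be positive")
    grid = mmap.grid
    nsh = grid.node_shape
    if patch_center is None:
        _, Ly, Lz = grid.extent
        patch_center = (grid.origin[1] + Ly / 2.0, grid.origin[2] + Lz / 2.0)
    yc, zc = patch_center

    fixed = np.ravel_multi_index(
        (
            np.repeat(np.arange(nsh[0]), nsh[1]),
            np.tile(np.arange(nsh[1]), nsh[0]),
            np.zeros(nsh[0] * nsh[1], dtype=int),
        ),
        nsh,
    )

    ys = grid.node_coords(1)
    zs = grid.node_coords(2)
    on_patch = (ys[:, None] - yc) ** 2 + (zs[None, :] - zc) ** 2 <= (
        patch_diameter / 2.0
    ) ** 2
    jy, jz = np.nonzero(on_patch)
    driven = np.ravel_multi_index((np.zeros_like(jy), jy, jz), nsh)
    driven = np.setdiff1d(driven, fixed)
    if driven.size == 0:
        raise ValueError(
            f"excitation patch (diameter {patch_diameter} m at {patch_center}) "
            "contains no nodes"
        )
    return BoundarySpec(
        fixed_nodes=fixed,
        driven_nodes=driven,
        drive_vector=np.array([amplitude, 0.0, 0.0], dtype=np.complex128),
        frequency=float(frequency),
    )


def shear_wavelength(params: ZenerParams, frequency: float) -> float:
    """Shear wavelength (m) from the storage modulus: (1/f) sqrt(G'/rho)."""
    g = complex_shear_modulus(params, frequency).G_storage
    return np.sqrt(g / params.rho) / frequency


def resolution_check(mmap: MaterialMap, frequency: float) -> float:
    """Minimum elements-per-shear-wavelength ratio over present materials.

    A harmonic FEM field needs on the order of ten elements per wavelength to
    be trustworthy; a ``UserWarning`` is emitted below that.
    """
    ratios = [
        shear_wavelength(mmap.params_of(lab), frequency) / mmap.grid.spacing
        for lab in mmap.present_labels
    ]
    ratio = float(min(ratios))
    if ratio < 10.0:
        warnings.warn(
            f"only {ratio:.1f} elements per shear wavelength at {frequency} Hz "
            "(ten are typically necessary)",
            stacklevel=2,
        )
    return ratio
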