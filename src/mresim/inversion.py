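"""Modulus recovery from complex displacement fields (modified integral method).

In a locally homogeneous viscoelastic medium the curl of the displacement
field, ``w = curl(u)``, satisfies the Helmholtz equation

    (G' + i G'') lap(w) + rho omega^2 w = 0,

because taking the curl eliminates the pressure (longitudinal) contribution.
Integrating the inner product of the conjugated equation with ``w`` over a
small test domain R gives a ratio-of-integrals formula that is robust to
pointwise zeros of ``lap(w)``:

    G' - i G'' = -rho omega^2 * int_R |w|^2 dx / int_R w . conj(lap w) dx.

The pipeline is: (optional mollification of u) -> curl by second-order
central differences -> (optional mollification of w) -> 7-point Laplacian ->
sliding 3x3x3-point Simpson quadrature around every interior voxel.  The 2-D
variant uses the in-plane scalar curl ``dy u_x`` minus ... precisely
``w = du_y/dx - du_x/dy`` on one slice, a 5-point Laplacian and a 3x3x1
window; it is what a single-slice acquisition permits, and it overestimates
stiffness whenever the wave has an out-of-plane component.

Differentiation masks: the curl is undefined on the one-node boundary rim,
the Laplacian grows the invalid rim by one more node, and a window is valid
only when every quadrature point is valid.  Voxels whose denominator
magnitude falls below ``guard`` times the volume maximum are masked rather
than producing outliers, as are voxels with nonpositive recovered storage
modulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .forward import HarmonicField
from .phantom import MaterialMap, VoxelGrid
from .rheology import ComplexModulus

__all__ = [
    "CurlField",
    "TestDomain",
    "Elastogram",
    "InversionOptions",
    "curl",
    "curl_2d",
    "mollify",
    "laplacian",
    "recover_modulus",
    "elastogram_3d",
    "elastogram_2d",
    "interior_roi_mask",
    "material_node_masks",
]


@dataclass(frozen=True)
class CurlField:
    """Curl (or Laplacian-of-curl) samples on grid nodes with a validity mask.

    ``values`` has a trailing component axis of length 3 in the 3-D variant
    and no trailing axis in the scalar 2-D variant.
    """

    grid: VoxelGrid
    values: np.ndarray
    mask: np.ndarray
    spacing: float

    @property
    def is_scalar(self) -> bool:
        return self.values.ndim == self.mask.ndim


@dataclass(frozen=True)
class TestDomain:
    """Local integration window: center node, odd point counts, point spacing."""

    __test__ = False  # not a test case, despite the name

    center: Tuple[int, ...]
    points_per_axis: Tuple[int, ...] = (3, 3, 3)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if any(n < 1 or (n > 1 and n % 2 == 0) for n in self.points_per_axis):
            raise ValueError("points_per_axis entries must be 1 or odd and >= 3")


@dataclass(frozen=True)
class Elastogram:
    """Recovered storage/loss modulus volumes (Pa) with validity mask."""

    grid: VoxelGrid
    storage: np.ndarray
    loss: np.ndarray
    valid_mask: np.ndarray
    frequency: float
    slice_index: int | None = None


@dataclass(frozen=True)
class InversionOptions:
    """Knobs of the elastogram sweep.

    mollify_u_m / mollify_w_m : Gaussian smoothing widths (m) applied to the
        displacement field before the curl and to the curl before the
        Laplacian; ``None`` disables (the default for noiseless simulated
        fields, where smoothing would only bias the wavenumber).
    stride : integration-point spacing of the sliding window in grid steps;
        enlarging it grows the test domain toward the half-wavelength
        guidance without adding points.
    guard : relative denominator threshold below which a voxel is masked.
    """

    mollify_u_m: float | None = None
    mollify_w_m: float | None = None
    stride: int = 1
    guard: float = 1e-8


def _central_diff(a: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Second-order central difference; boundary entries are left as zero."""
    out = np.zeros_like(a)
    sl_lo = [slice(None)] * a.ndim
    sl_hi = [slice(None)] * a.ndim
    sl_in = [slice(None)] * a.ndim
    sl_lo[axis] = slice(0, -2)
    sl_hi[axis] = slice(2, None)
    sl_in[axis] = slice(1, -1)
    out[tuple(sl_in)] = (a[tuple(sl_hi)] - a[tuple(sl_lo)]) / (2.0 * h)
    return out


def _rim_mask(shape: Tuple[int, ...]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    inner = tuple(slice(1, -1) for _ in shape)
    mask[inner] = True
    return mask


def curl(field: HarmonicField) -> CurlField:
    """w = curl(u) by central differences; the one-node boundary rim is masked."""
    if any(n < 3 for n in field.grid.node_shape):
        raise ValueError("curl needs at least 3 nodes per axis")
    h = field.grid.spacing
    u = field.values
    d = lambda comp, axis: _central_diff(u[..., comp], axis, h)
    w = np.stack(
        [
            d(2, 1) - d(1, 2),
            d(0, 2) - d(2, 0),
            d(1, 0) - d(0, 1),
        ],
        axis=-1,
    )
    return CurlField(
        grid=field.grid, values=w, mask=_rim_mask(field.grid.node_shape), spacing=h
    )


def curl_2d(field: HarmonicField, slice_index: int) -> CurlField:
    """Scalar in-plane curl w = du_y/dx - du_x/dy on one z slice."""
    nz = field.grid.node_shape[2]
    if not 0 <= slice_index < nz:
        raise ValueError(f"slice_index {slice_index} outside [0, {nz})")
    if any(n < 3 for n in field.grid.node_shape[:2]):
        raise ValueError("2-D curl needs at least 3 nodes per in-plane axis")
    h = field.grid.spacing
    u = field.values[:, :, slice_index, :]
    w = _central_diff(u[..., 1], 0, h) - _central_diff(u[..., 0], 1, h)
    return CurlField(
        grid=field.grid, values=w, mask=_rim_mask(w.shape), spacing=h
    )


def mollify(
    values: np.ndarray,
    width: float,
    spacing: float,
    n_spatial: int | None = None,
) -> np.ndarray:
    """Gaussian mollification: convolution with a normalized kernel of
    standard deviation ``width`` (m), truncated at 3 sigma, reflective
    boundaries.  ``width = 0`` is the identity.

    ``n_spatial`` is the number of leading spatial axes; trailing axes (e.g.
    a vector-component axis) are not smoothed.  By default a trailing axis of
    length 3 on a >= 3-D array is treated as components.
    """
    if width < 0:
        raise ValueError("mollification width must be nonnegative")
    if width == 0:
        return values.copy()
    sigma_vox = width / spacing
    if n_spatial is None:
        n_spatial = values.ndim - (
            1 if values.shape[-1] == 3 and values.ndim >= 3 else 0
        )
    sigmas = [sigma_vox] * n_spatial + [0] * (values.ndim - n_spatial)

    def smooth(a):
        return ndimage.gaussian_filter(a, sigma=sigmas, mode="reflect", truncate=3.0)

    if np.iscomplexobj(values):
        return smooth(values.real) + 1j * smooth(values.imag)
    return smooth(values)


def mollify_field(cf: CurlField, width: float) -> CurlField:
    """Mollify a curl field, preserving grid metadata and mask."""
    return CurlField(
        grid=cf.grid,
        values=mollify(cf.values, width, cf.spacing, n_spatial=cf.mask.ndim),
        mask=cf.mask.copy(),
        spacing=cf.spacing,
    )


def laplacian(cf: CurlField) -> CurlField:
    """Component-wise 7-point (3-D) / 5-point (2-D) Laplacian.

    The invalid rim grows by one node: a node is valid only when itself and
    all stencil neighbors were valid.
    """
    mask = cf.mask
    ndim = mask.ndim
    if any(n < 3 for n in mask.shape):
        raise ValueError("laplacian needs at least 3 valid nodes per axis")
    h2 = cf.spacing**2
    vals = cf.values
    out = np.zeros_like(vals)
    inner = tuple(slice(1, -1) for _ in range(ndim))
    acc = -2.0 * ndim * vals[inner + (Ellipsis,)]
    for axis in range(ndim):
        lo = tuple(
            slice(0, -2) if a == axis else slice(1, -1) for a in range(ndim)
        )
        hi = tuple(
            slice(2, None) if a == axis else slice(1, -1) for a in range(ndim)
        )
        acc = acc + vals[lo + (Ellipsis,)] + vals[hi + (Ellipsis,)]
    out[inner + (Ellipsis,)] = acc / h2

    structure = ndimage.generate_binary_structure(ndim, 1)
    new_mask = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return CurlField(grid=cf.grid, values=out, mask=new_mask, spacing=cf.spacing)


def _simpson_weights(n: int, h: float) -> np.ndarray:
    """Composite Simpson weights for n equispaced points (n = 1 or odd)."""
    if n == 1:
        return np.array([1.0])
    w = np.zeros(n)
    w[0] = w[-1] = 1.0
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


def _dot_conj(w: np.ndarray, lap_w: np.ndarray, scalar: bool) -> np.ndarray:
    if scalar:
        return w * np.conj(lap_w)
    return np.sum(w * np.conj(lap_w), axis=-1)


def _abs2(w: np.ndarray, scalar: bool) -> np.ndarray:
    if scalar:
        return np.abs(w) ** 2
    return np.sum(np.abs(w) ** 2, axis=-1)


def recover_modulus(
    w: CurlField,
    lap_w: CurlField,
    domain: TestDomain,
    rho: float,
    frequency: float,
) -> ComplexModulus:
    """Complex shear modulus over one test domain.

    Evaluates ``G' - i G'' = -rho omega^2 * (int |w|^2) / (int w . conj(lap w))``
    with composite-Simpson quadrature on the window points.  The result is
    invariant to any nonzero complex rescaling of ``w``.
    """
    scalar = w.is_scalar
    ndim = w.mask.ndim
    pts = domain.points_per_axis[:ndim]
    stride = max(1, int(round(domain.spacing / w.spacing)))
    axes_idx = []
    for d in range(ndim):
        half = (pts[d] - 1) // 2
        idx = domain.center[d] + stride * np.arange(-half, half + 1)
        if idx[0] < 0 or idx[-1] >= w.mask.shape[d]:
            raise ValueError("test domain extends outside the field")
        axes_idx.append(idx)
    window = np.ix_(*axes_idx)
    if not (w.mask[window].all() and lap_w.mask[window].all()):
        raise ValueError("test domain touches masked (invalid) nodes")

    weight = np.ones(())
    for d in range(ndim):
        w1 = _simpson_weights(pts[d], stride * w.spacing)
        weight = np.multiply.outer(weight, w1)

    num = np.sum(weight * _abs2(w.values[window], scalar))
    den = np.sum(weight * _dot_conj(w.values[window], lap_w.values[window], scalar))
    if abs(den) == 0:
        raise ZeroDivisionError("vanishing denominator integral over the test domain")
    omega = 2.0 * np.pi * frequency
    ratio = num / den
    g_storage = -rho * omega**2 * ratio.real
    g_loss = rho * omega**2 * ratio.imag
    return ComplexModulus(
        G_storage=g_storage,
        G_loss=max(g_loss, 0.0),
        K_storage=g_storage,
        K_loss=max(g_loss, 0.0),
        frequency=frequency,
    )


def _sliding_elastogram(
    w: CurlField,
    lap_w: CurlField,
    rho: float,
    frequency: float,
    stride: int,
    guard: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 3(-point)-per-axis Simpson sweep over every valid center."""
    scalar = w.is_scalar
    ndim = w.mask.ndim
    kernel = np.ones(())
    for _ in range(ndim):
        w1 = np.zeros(2 * stride + 1)
        w1[[0, stride, 2 * stride]] = _simpson_weights(3, stride * w.spacing)
        kernel = np.multiply.outer(kernel, w1)

    invalid = ~(w.mask & lap_w.mask)
    support = np.zeros_like(kernel)
    support[kernel != 0] = 1.0
    touched = ndimage.convolve(invalid.astype(float), support, mode="constant", cval=1.0)
    valid = touched == 0

    abs2 = np.where(invalid, 0.0, _abs2(w.values, scalar))
    dotc = np.where(invalid, 0.0, _dot_conj(w.values, lap_w.values, scalar))
    num = ndimage.convolve(abs2, kernel, mode="constant", cval=0.0)
    den_re = ndimage.convolve(dotc.real, kernel, mode="constant", cval=0.0)
    den_im = ndimage.convolve(dotc.imag, kernel, mode="constant", cval=0.0)
    den = den_re + 1j * den_im

    den_mag = np.abs(den)
    den_floor = guard * (den_mag[valid].max() if valid.any() else 0.0)
    valid &= den_mag > den_floor

    omega = 2.0 * np.pi * frequency
    ratio = np.zeros_like(den)
    np.divide(num, den, out=ratio, where=valid)
    storage = -rho * omega**2 * ratio.real
    loss = rho * omega**2 * ratio.imag
    valid &= storage > 0
    storage[~valid] = 0.0
    loss[~valid] = 0.0
    return storage, loss, valid


def _require_rotational(field: HarmonicField, w: CurlField) -> None:
    """Reject fields whose curl is pure differencing roundoff (e.g. gradient
    fields): every voxel of such an elastogram would be invalid."""
    w_scale = np.abs(w.values[w.mask]).max() if w.mask.any() else 0.0
    floor = 1e-10 * np.abs(field.values).max() / field.grid.spacing
    if w_scale < floor:
        raise ValueError(
            "displacement field is numerically curl-free: all voxels invalid"
        )


def elastogram_3d(
    field: HarmonicField,
    rho: float,
    frequency: float | None = None,
    opts: InversionOptions = InversionOptions(),
) -> Elastogram:
    """Full-volume 3-D inversion sweep (3x3x3-point windows)."""
    frequency = field.frequency if frequency is None else frequency
    work = field
    if opts.mollify_u_m:
        work = HarmonicField(
            grid=field.grid,
            values=mollify(field.values, opts.mollify_u_m, field.grid.spacing),
            frequency=field.frequency,
        )
    w = curl(work)
    _require_rotational(field, w)
    if opts.mollify_w_m:
        w = mollify_field(w, opts.mollify_w_m)
    lap_w = laplacian(w)
    storage, loss, valid = _sliding_elastogram(
        w, lap_w, rho, frequency, opts.stride, opts.guard
    )
    if not valid.any():
        raise ValueError("all voxels invalid: field too small or curl-free")
    return Elastogram(
        grid=field.grid,
        storage=storage,
        loss=loss,
        valid_mask=valid,
        frequency=frequency,
    )


def elastogram_2d(
    field: HarmonicField,
    slice_index: int,
    rho: float,
    frequency: float | None = None,
    opts: InversionOptions = InversionOptions(),
) -> Elastogram:
    """Single-slice 2-D inversion (in-plane curl, 3x3x1-point windows)."""
    frequency = field.frequency if frequency is None else frequency
    work = field
    if opts.mollify_u_m:
        work = HarmonicField(
            grid=field.grid,
            values=mollify(field.values, opts.mollify_u_m, field.grid.spacing),
            frequency=field.frequency,
        )
    w = curl_2d(work, slice_index)
    _require_rotational(field, w)
    if opts.mollify_w_m:
        w = mollify_field(w, opts.mollify_w_m)
    lap_w = laplacian(w)
    storage, loss, valid = _sliding_elastogram(
        w, lap_w, rho, frequency, opts.stride, opts.guard
    )
    if not valid.any():
        raise ValueError("all voxels invalid on the requested slice")
    return Elastogram(
        grid=field.grid,
        storage=storage,
        loss=loss,
        valid_mask=valid,
        frequency=frequency,
        slice_index=slice_index,
    )


def interior_roi_mask(mask: np.ndarray, margin: int = 5) -> np.ndarray:
    """Restrict a validity mask to nodes at least ``margin`` nodes from every
    array boundary (the averaging region for whole-volume statistics)."""
    out = np.zeros_like(mask)
    if all(n > 2 * margin for n in mask.shape):
        inner = tuple(slice(margin, n - margin) for n in mask.shape)
        out[inner] = mask[inner]
    return out


def material_node_masks(
    mmap: MaterialMap, interface_margin: int = 2
) -> dict[int, np.ndarray]:
    """Node masks per material, eroded away from material interfaces.

    A node is attributed to a material only when all adjacent elements carry
    that label; the mask is then eroded ``interface_margin`` times so that
    statistics exclude nodes whose inversion stencils straddle the interface.
    """
    nsh = mmap.grid.node_shape
    out: dict[int, np.ndarray] = {}
    structure = ndimage.generate_binary_structure(3, 1)
    for lab in mmap.present_labels:
        elem = mmap.labels == lab
        padded = np.zeros(tuple(n + 2 for n in mmap.labels.shape), dtype=bool)
        padded[1:-1, 1:-1, 1:-1] = elem
        node = np.ones(nsh, dtype=bool)
        for ox in (0, 1):
            for oy in (0, 1):
                for oz in (0, 1):
                    node &= padded[
                        ox : ox + nsh[0], oy : oy + nsh[1], oz : oz + nsh[2]
                    ]
        if interface_margin > 0:
            node = ndimage.binary_erosion(
                node, structure=structure, iterations=interface_margin, border_value=0
            )
        out[int(lab)] = node
    return out
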