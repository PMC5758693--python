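"""Motion-encoding-gradient (MEG) phase encoding and decoding.

A harmonic tissue displacement ``u(t, x) = Re[U(x) exp(i(omega t + phi))]``
moving through an oscillating field gradient ``G(t) = G0 * d * cos(omega t)``
accumulates the spin phase

    theta(x) = gamma * int_{t0}^{t0 + N/F} u(t, x) . G(t) dt
             = gamma * G0 * N / (2 F) * |U.d| * cos(arg(U.d) + phi),

where gamma is the gyromagnetic ratio, d the (unit) gradient direction, N the
number of encoding cycles and F the gradient frequency (synchronized with the
vibration).  The closed form is exact for whole cycles; a trapezoid
quadrature of the integral is provided as an independent cross-check.

Acquiring K images at motion phase offsets ``phi_k`` (default 4, equally
spaced over one cycle) and fitting ``theta_k = a cos(phi_k) + b sin(phi_k) + c``
per voxel recovers the complex projection ``U.d = (a - i b) * 2F/(gamma G0 N)``;
the intercept absorbs any motion-free background phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .forward import HarmonicField
from .phantom import VoxelGrid

__all__ = ["MEGSpec", "PhaseImage", "encode_phase", "encode_phase_quadrature",
           "decode_displacement", "phase_sensitivity"]

#: gyromagnetic ratio of the proton, rad / (s T)
GAMMA_PROTON = 2.675e8


@dataclass(frozen=True)
class MEGSpec:
    """Motion-encoding gradient parameters."""

    gradient_amplitude: float  # T/m
    frequency: float  # Hz
    cycles: int = 4
    gamma: float = GAMMA_PROTON
    gradient_direction: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        d = np.asarray(self.gradient_direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, rtol=1e-9):
            raise ValueError("gradient_direction must be a unit vector")
        object.__setattr__(self, "gradient_direction", tuple(d))


@dataclass(frozen=True)
class PhaseImage:
    """Phase-shift volume (rad) on grid nodes; wrapped to (-pi, pi] only when
    ``wrapped`` is set."""

    grid: VoxelGrid
    values: np.ndarray
    wrapped: bool = False


def phase_sensitivity(meg: MEGSpec) -> float:
    """Radians of phase per meter of in-phase displacement amplitude:
    gamma * G0 * N / (2 F)."""
    return meg.gamma * meg.gradient_amplitude * meg.cycles / (2.0 * meg.frequency)


def _projection(field: HarmonicField, meg: MEGSpec) -> np.ndarray:
    d = np.asarray(meg.gradient_direction)
    return field.values @ d


def encode_phase(
    field: HarmonicField,
    meg: MEGSpec,
    motion_phase_offset: float = 0.0,
    wrap: bool = False,
) -> PhaseImage:
    """Phase image from a harmonic displacement field (closed form)."""
    if meg.frequency != field.frequency:
        warnings.warn(
            f"MEG frequency {meg.frequency} Hz differs from motion frequency "
            f"{field.frequency} Hz; encoding assumes synchronized MRE",
            stacklevel=2,
        )
    if meg.gradient_amplitude == 0:
        warnings.warn("zero gradient amplitude encodes no phase", stacklevel=2)
    proj = _projection(field, meg)
    theta = phase_sensitivity(meg) * np.real(proj * np.exp(1j * motion_phase_offset))
    if wrap:
        theta = np.angle(np.exp(1j * theta))
    return PhaseImage(grid=field.grid, values=theta, wrapped=wrap)


def encode_phase_quadrature(
    field: HarmonicField,
    meg: MEGSpec,
    motion_phase_offset: float = 0.0,
    n_steps: int = 10_000,
) -> PhaseImage:
    """Trapezoid quadrature of the encoding integral (cross-check path)."""
    proj = _projection(field, meg)
    omega = 2.0 * np.pi * field.frequency
    t = meg.start_time + np.linspace(0.0, meg.cycles / meg.frequency, n_steps + 1)
    u_t = np.real(
        proj[..., None] * np.exp(1j * (omega * t + motion_phase_offset))
    )
    g_t = meg.gradient_amplitude * np.cos(2.0 * np.pi * meg.frequency * t)
    theta = meg.gamma * np.trapezoid(u_t * g_t, t, axis=-1)
    return PhaseImage(grid=field.grid, values=theta, wrapped=False)


def decode_displacement(
    phases: Sequence[PhaseImage],
    offsets: Sequence[float],
    meg: MEGSpec,
) -> np.ndarray:
    """Complex displacement projection U.d (m) from phase images at known
    motion phase offsets, by per-voxel linear least squares with intercept."""
    if len(phases) != len(offsets):
        raise ValueError("need one phase image per offset")
    if len(phases) < 2:
        raise ValueError("at least two phase offsets are required")
    offs = np.asarray(offsets, dtype=float)
    # the DC (intercept) column rejects motion-free background phase; it needs
    # a third observation to stay determined
    if len(phases) >= 3:
        X = np.column_stack([np.cos(offs), np.sin(offs), np.ones_like(offs)])
    else:
        X = np.column_stack([np.cos(offs), np.sin(offs)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: offsets do not span a cycle")
    theta = np.stack([p.values.reshape(-1) for p in phases], axis=0)
    coef, *_ = np.linalg.lstsq(X, theta, rcond=None)
    a, b = coef[0], coef[1]
    proj = (a - 1j * b) / phase_sensitivity(meg)
    return proj.reshape(phases[0].values.shape)
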