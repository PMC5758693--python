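"""Zener (standard linear solid) viscoelasticity.

The Zener model is a spring of constant ``mu0`` in parallel with a Maxwell
branch: a spring ``mu1`` in series with a dashpot of viscosity
``eta1 = mu1 * tau1``.  Its shear relaxation function is

    G(t) = mu0 + mu1 * exp(-t / tau1),

so the material relaxes from the instantaneous modulus ``mu0 + mu1`` to the
long-time equilibrium modulus ``mu0`` with relaxation time ``tau1``.  The
bulk relaxation modulus shares the same time dependence, scaled through the
Poisson ratio ``nu``:

    K(t) = (2/3) * (1 + nu) / (1 - 2 nu) * G(t).

Under steady harmonic shear at angular frequency ``omega = 2*pi*f`` the model
has the complex shear modulus ``G* = G' + i G''`` with

    G'  = mu0 + mu1 * (omega * eta1)**2 / (mu1**2 + (omega * eta1)**2)
    G'' =       mu1**2 * (omega * eta1) / (mu1**2 + (omega * eta1)**2)

``G'`` (storage modulus) rises monotonically from ``mu0`` to ``mu0 + mu1``;
``G''`` (loss modulus) peaks at ``mu1 / 2`` when ``omega = 1 / tau1``.

All quantities are SI (Pa, s, kg/m^3); callers convert to kPa only for
reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZenerParams",
    "ComplexModulus",
    "bulk_to_shear_ratio",
    "shear_relaxation",
    "bulk_relaxation",
    "complex_shear_modulus",
]


@dataclass(frozen=True)
class ZenerParams:
    """Material constants of a Zener solid.

    Parameters
    ----------
    mu0 : float
        Equilibrium shear spring constant, Pa.
    mu1 : float
        Maxwell-branch shear spring constant, Pa.
    tau1 : float
        Relaxation time, s.  The dashpot viscosity is implied:
        ``eta1 = mu1 * tau1``.
    nu : float
        Poisson's ratio, dimensionless, in (0, 0.5).  Soft tissue is nearly
        incompressible (``nu`` close to 0.5).
    rho : float
        Mass density, kg/m^3.
    """

    mu0: float
    mu1: float
    tau1: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if not self.mu1 > 0:
            raise ValueError(f"mu1 must be positive, got {self.mu1}")
        if not self.tau1 > 0:
            raise ValueError(f"tau1 must be positive, got {self.tau1}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"nu must lie in (0, 0.5), got {self.nu}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")

    @property
    def eta1(self) -> float:
        """Dashpot viscosity, Pa s.  Stored implicitly so tau1 == eta1/mu1
        holds by construction."""
        return self.mu1 * self.tau1


@dataclass(frozen=True)
class ComplexModulus:
    """Storage/loss shear and bulk moduli at one frequency (Pa, Hz)."""

    G_storage: float
    G_loss: float
    K_storage: float
    K_loss: float
    frequency: float

    def __post_init__(self) -> None:
        if not self.G_storage > 0:
            raise ValueError("G_storage must be positive")
        if self.G_loss < 0:
            raise ValueError("G_loss must be nonnegative")
        if not self.K_storage > 0:
            raise ValueError("K_storage must be positive")
        if self.K_loss < 0:
            raise ValueError("K_loss must be nonnegative")

    @property
    def shear(self) -> complex:
        """Complex shear modulus G' + i G'', Pa."""
        return complex(self.G_storage, self.G_loss)

    @property
    def bulk(self) -> complex:
        """Complex bulk modulus K' + i K'', Pa."""
        return complex(self.K_storage, self.K_loss)

    @property
    def lame_lambda(self) -> complex:
        """Complex first Lame parameter, lambda* = K* - (2/3) G*, Pa."""
        return self.bulk - 2.0 / 3.0 * self.shear


def bulk_to_shear_ratio(nu: float) -> float:
    """Ratio K(t)/G(t) = (2/3)(1+nu)/(1-2nu) implied by the Poisson ratio."""
    if nu >= 0.5:
        raise ValueError("nu = 0.5 is the singular incompressible limit")
    return 2.0 / 3.0 * (1.0 + nu) / (1.0 - 2.0 * nu)


def shear_relaxation(params: ZenerParams, t):
    """Shear relaxation modulus G(t) = mu0 + mu1 exp(-t/tau1), Pa.

    ``t`` may be a scalar or array of nonnegative times in seconds.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation time argument t must be nonnegative")
    out = params.mu0 + params.mu1 * np.exp(-t / params.tau1)
    return float(out) if out.ndim == 0 else out


def bulk_relaxation(params: ZenerParams, t):
    """Bulk relaxation modulus K(t) = (2/3)((1+nu)/(1-2nu)) G(t), Pa."""
    return bulk_to_shear_ratio(params.nu) * shear_relaxation(params, t)


def complex_shear_modulus(params: ZenerParams, f: float) -> ComplexModulus:
    """Complex moduli of the Zener solid at excitation frequency ``f`` (Hz).

    Uses angular frequency ``omega = 2*pi*f``.  The bulk components carry the
    same Poisson scaling as the relaxation functions, so the loss tangent of
    shear and bulk responses is identical.
    """
    if not f > 0:
        raise ValueError(f"frequency must be positive, got {f}")
    omega = 2.0 * math.pi * f
    we = omega * params.eta1
    denom = params.mu1**2 + we**2
    g_storage = params.mu0 + params.mu1 * we**2 / denom
    g_loss = params.mu1**2 * we / denom
    ratio = bulk_to_shear_ratio(params.nu)
    return ComplexModulus(
        G_storage=g_storage,
        G_loss=g_loss,
        K_storage=ratio * g_storage,
        K_loss=ratio * g_loss,
        frequency=f,
    )
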