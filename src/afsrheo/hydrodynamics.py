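"""Near-wall drag corrections to Stokes' law for a translating sphere.

A sphere of radius R whose center sits a distance L from a plane wall feels
an increased viscous drag; Stokes' law holds with an effective viscosity
eta_eff = lambda * eta_fluid.  Two classical corrections are provided:

* Brenner's exact bipolar-coordinate series for translation perpendicular to
  the wall (the geometry of an acoustically lifted or falling bead),
* Faxen's reciprocal polynomial for translation parallel to the wall (the
  optical-tweezers geometry, kept for comparison).

Both factors are >= 1 and approach 1 far from the wall.  The perpendicular
(Brenner) factor diverges like R/gap as the sphere approaches contact, which
is why the motion integrator enforces a minimum surface clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "WallDragMethod",
    "WallDragSpec",
    "brenner_lambda",
    "faxen_lambda",
    "effective_viscosity",
]


class WallDragMethod(str, Enum):
    BRENNER = "brenner"
    FAXEN = "faxen"
    NONE = "none"


def _check_geometry(L: float, R: float) -> None:
    if not (math.isfinite(L) and math.isfinite(R)):
        raise ValueError("L and R must be finite")
    if R <= 0:
        raise ValueError("bead radius must be positive")
    if L <= R:
        raise ValueError("bead intersects surface: require L > R (L = z + R)")


def brenner_lambda(L: float, R: float, n_terms: int = 100) -> float:
    """Perpendicular wall-drag factor from Brenner's exact series.

    ``L`` is the wall-to-center distance, ``R`` the sphere radius.  With
    cosh(a) = L/R the factor is

        lambda = (4/3) sinh a * sum_{n=1}^{N} n(n+1)/((2n-1)(2n+3)) *
                 [ (2 sinh((2n+1)a) + (2n+1) sinh(2a)) /
                   (4 sinh^2((n+1/2)a) - (2n+1)^2 sinh^2 a) - 1 ]

    evaluated here in an exponentially rescaled form that is stable for
    large L/R.  The default truncation is 100 terms.
    """
    _check_geometry(L, R)
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    a = math.acosh(L / R)
    n = np.arange(1, n_terms + 1, dtype=float)
    # Multiply numerator and denominator by exp(-(2n+1)a) to avoid overflow.
    e = np.exp
    num = (1.0 - e(-2.0 * (2 * n + 1) * a)) + (2 * n + 1) / 2.0 * (
        e(-(2 * n - 1) * a) - e(-(2 * n + 3) * a)
    )
    den = (1.0 - e(-(2 * n + 1) * a)) ** 2 - (2 * n + 1) ** 2 * (
        e(-(2 * n - 1) * a) - 2.0 * e(-(2 * n + 1) * a) + e(-(2 * n + 3) * a)
    ) / 4.0
    coeff = n * (n + 1) / ((2 * n - 1) * (2 * n + 3))
    lam = (4.0 / 3.0) * math.sinh(a) * float(np.sum(coeff * (num / den - 1.0)))
    return max(lam, 1.0)


def faxen_lambda(L: float, R: float) -> float:
    """Parallel wall-drag factor (Faxen), order 5 in s = R/L."""
    _check_geometry(L, R)
    s = R / L
    denom = 1.0 - (9.0 / 16.0) * s + (1.0 / 8.0) * s**3 - (45.0 / 256.0) * s**4 - (1.0 / 16.0) * s**5
    return 1.0 / denom


@dataclass(frozen=True)
class WallDragSpec:
    """Choice of wall correction for a bead of radius ``bead_radius`` [m]."""

    method: WallDragMethod = WallDragMethod.BRENNER
    bead_radius: float = 5e-6   # m
    n_terms: int = 100

    def __post_init__(self) -> None:
        if self.bead_radius <= 0:
            raise ValueError("bead radius must be positive")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        object.__setattr__(self, "method", WallDragMethod(self.method))

    def lam(self, z: float) -> float:
        """Drag factor at surface-to-bead-bottom distance ``z`` [m]."""
        if self.method is WallDragMethod.NONE:
            return 1.0
        L = z + self.bead_radius
        if self.method is WallDragMethod.BRENNER:
            return brenner_lambda(L, self.bead_radius, self.n_terms)
        return faxen_lambda(L, self.bead_radius)


def effective_viscosity(eta_fluid: float, spec: WallDragSpec, z: float) -> float:
    """eta_eff = lambda(z) * eta_fluid for a bead at height ``z`` [m]."""
    if eta_fluid <= 0:
        raise ValueError("fluid viscosity must be positive")
    if z < 0:
        raise ValueError("bead height must be non-negative")
    return spec.lam(z) * eta_fluid
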