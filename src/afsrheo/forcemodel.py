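"""Acoustic force profile, effective gravity and overdamped bead dynamics.

The standing acoustic pressure wave exerts a height-dependent force

    F_ac(z) = f0 * k_p * sin(2 * (k_p * z + phi_p))

on a bead at height ``z`` above the chamber bottom (positive force = up,
away from the surface).  Together with the buoyancy-corrected weight and
wall-corrected Stokes drag this gives the overdamped equation of motion

    dz/dt = (F_ac(z) - F_grav) / (6 pi R eta_eff(z)),

which is integrated numerically to predict calibration pull and fall
trajectories.  Inertia and Brownian motion are neglected; measurement noise
is added only by the synthetic-data generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

from .fluidprops import FluidState
from .hydrodynamics import WallDragSpec

__all__ = [
    "G_STANDARD",
    "Z_MIN_DEFAULT",
    "BeadSpec",
    "AcousticForceParams",
    "Trajectory",
    "acoustic_force",
    "node_position",
    "effective_gravity",
    "integrate_motion",
    "simulate_fall",
]

G_STANDARD = 9.81       # m/s^2
Z_MIN_DEFAULT = 10e-9   # m; below this clearance the bead counts as landed


@dataclass(frozen=True)
class BeadSpec:
    """Probe bead: 10 um polystyrene by default (density 1050 kg/m^3)."""

    radius: float = 5e-6          # m
    density: float = 1050.0       # kg/m^3
    compressibility: float | None = None  # 1/Pa, metadata only
    coating: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0:
            raise ValueError("bead radius and density must be positive")

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3


@dataclass(frozen=True)
class AcousticForceParams:
    """Force-profile triple (f0, k_p, phi_p) — the unit of calibration.

    ``f0`` is in pN*um, ``k_p`` in 1/um, ``phi_p`` in rad, matching the
    units in which calibrations are reported.
    """

    f0: float                     # pN*um
    k_p: float                    # 1/um
    phi_p: float                  # rad
    amplitude_pct: float = 0.0    # drive amplitude this profile was fit at
    pressure_amplitude: float | None = None  # Pa, metadata only
    correction_method: str = "brenner"

    def __post_init__(self) -> None:
        if self.f0 < 0:
            raise ValueError("f0 must be non-negative")
        if self.k_p <= 0:
            raise ValueError("k_p must be positive")
        if not 0.0 <= self.phi_p < math.pi:
            raise ValueError("phi_p must lie in [0, pi)")


@dataclass
class Trajectory:
    """Uniformly sampled bead track (SI units internally)."""

    time: np.ndarray                 # s
    z: np.ndarray                    # m
    bead_id: str = "bead0"
    x: np.ndarray | None = None      # um, field-of-view coordinate
    y: np.ndarray | None = None      # um
    amplitude: np.ndarray | None = None  # % drive per sample
    temperature: float | None = None     # degC
    phase: np.ndarray | None = None      # str labels, e.g. "on"/"off"
    at_surface: np.ndarray | None = None # bool flags from the integrator

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.z.shape:
            raise ValueError("time and z must be 1-D arrays of equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.z < 0):
            raise ValueError("z must be non-negative")
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if np.any(self.amplitude < 0):
                raise ValueError("amplitude must be non-negative")

    @property
    def sampling_rate(self) -> float:
        dt = np.median(np.diff(self.time))
        return 1.0 / float(dt)


def acoustic_force(z: float | np.ndarray, params: AcousticForceParams) -> float | np.ndarray:
    """Acoustic force [N] at height ``z`` [m]; positive pulls up.

    f0 [pN*um] * k_p [1/um] is a force in pN, converted to N on return.
    """
    z_um = np.asarray(z, dtype=float) * 1e6
    f_pn = params.f0 * params.k_p * np.sin(2.0 * (params.k_p * z_um + params.phi_p))
    f = f_pn * 1e-12
    return f if np.ndim(z) else float(f)


def node_position(params: AcousticForceParams) -> float:
    """Smallest positive height [m] where the force crosses zero downward.

    Solves sin(2(k_p z + phi_p)) = 0 at the pull-to-push sign change:
    z = (pi/2 - phi_p)/k_p, shifted by half-periods until positive.
    """
    if params.k_p <= 0:
        raise ValueError("k_p must be positive")
    z_um = (math.pi / 2.0 - params.phi_p) / params.k_p
    while z_um <= 0:
        z_um += math.pi / params.k_p
    return z_um * 1e-6


def effective_gravity(bead: BeadSpec, fluid: FluidState) -> float:
    """Buoyancy-corrected weight [N], positive = downward."""
    return (bead.density - fluid.density_corrected) * bead.volume * G_STANDARD


def _drag_coefficient(bead: BeadSpec, fluid: FluidState, drag: WallDragSpec, z: float) -> float:
    return 6.0 * math.pi * bead.radius * fluid.viscosity * drag.lam(max(z, 0.0))


_LAM_TABLE_ZHI = 200e-6  # m; beads never exceed the chamber height


@lru_cache(maxsize=32)
def _lam_table(drag: WallDragSpec, z_min: float, z_hi: float) -> tuple[np.ndarray, np.ndarray]:
    log_grid = np.linspace(math.log(z_min), math.log(z_hi), 512)
    lam_tab = np.array([drag.lam(math.exp(lz)) for lz in log_grid])
    return log_grid, lam_tab


def integrate_motion(
    params: AcousticForceParams | None,
    bead: BeadSpec,
    fluid: FluidState,
    drag: WallDragSpec,
    z0: float,
    t_grid: np.ndarray,
    z_min: float = Z_MIN_DEFAULT,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the overdamped equation of motion on ``t_grid``.

    ``params=None`` means zero acoustic force (gravity-only fall).  The
    trajectory is clipped at ``z_min``; once the bead reaches the surface
    cutoff it stays there (velocity 0) and samples are flagged
    ``at_surface``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    z0 = max(float(z0), z_min)
    f_grav = effective_gravity(bead, fluid)
    drag0 = 6.0 * math.pi * bead.radius * fluid.viscosity

    # The wall-drag series is the cost center of the right-hand side; it is
    # smooth in log z, so tabulate once per drag spec and interpolate.
    from .hydrodynamics import WallDragMethod

    if drag.method is WallDragMethod.NONE:
        lam_of = lambda z: 1.0  # noqa: E731
    else:
        z_hi = max(4.0 * z0, _LAM_TABLE_ZHI)
        log_grid, lam_tab = _lam_table(drag, z_min, z_hi)

        def lam_of(z: float) -> float:
            return float(np.interp(math.log(min(max(z, z_min), z_hi)), log_grid, lam_tab))

    def rhs(t: float, y: np.ndarray) -> list[float]:
        z = max(y[0], z_min)
        f_ac = acoustic_force(z, params) if params is not None else 0.0
        return [(f_ac - f_grav) / (drag0 * lam_of(z))]

    def landed(t: float, y: np.ndarray) -> float:
        return y[0] - z_min

    landed.terminal = True
    landed.direction = -1.0

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [z0],
        t_eval=t_grid,
        events=landed,
        method="RK45",
        rtol=rtol,
        atol=atol,
        max_step=(t_grid[-1] - t_grid[0]) / 10.0,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"motion integration failed: {sol.message}")

    z = np.full(t_grid.shape, z_min)
    at_surface = np.ones(t_grid.shape, dtype=bool)
    n = sol.y.shape[1]
    z[:n] = np.maximum(sol.y[0], z_min)
    at_surface[:n] = z[:n] <= z_min * (1 + 1e-9)
    return Trajectory(time=t_grid, z=z, at_surface=at_surface)


def simulate_fall(
    z0: float,
    bead: BeadSpec,
    fluid: FluidState,
    drag: WallDragSpec,
    t_grid: np.ndarray,
    z_min: float = Z_MIN_DEFAULT,
) -> Trajectory:
    """Gravity-only fall from ``z0`` [m]; used for calibration validation."""
    return integrate_motion(None, bead, fluid, drag, z0, t_grid, z_min=z_min)
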