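"""Stokes force calibration (SFC) and the spatial conversion map.

Switching on the acoustic drive pulls a bead up from the chamber surface;
its overdamped trajectory through the wall-corrected viscous medium encodes
the force profile.  The SFC fits the force-profile triple (f0, k_p, phi_p)
by least squares between the measured pull trace and trajectories predicted
by integrating the equation of motion.  Switching the drive off leaves only
gravity: the fall trace is predicted with *no* free parameters and its
coefficient of determination R^2_off validates the drag model — correct
wall correction (perpendicular/Brenner) predicts the fall, wrong ones do
not.

From per-amplitude force profiles, the force at a 1 um reference height
gives the quadratic amplitude-to-force conversion F = c V^2.  Calibrating
many beads across the field of view yields a spatial map of c(x, y), which
is QC-filtered, position-merged and interpolated at measurement time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.optimize import least_squares
from scipy.spatial import QhullError

from .fluidprops import FluidState
from .forcemodel import (
    AcousticForceParams,
    BeadSpec,
    Trajectory,
    acoustic_force,
    integrate_motion,
    simulate_fall,
)
from .hydrodynamics import WallDragSpec

__all__ = [
    "QCRules",
    "StokesCalibration",
    "ConversionMap",
    "fit_force_model",
    "validate_fall",
    "fit_bead_density",
    "conversion_factor",
    "build_spatial_map",
    "lookup_conversion",
    "FOV_UM",
]

FOV_UM = (678.40, 542.72)   # camera field of view, um


@dataclass(frozen=True)
class QCRules:
    """Bead-level quality-control thresholds for calibration traces."""

    min_displacement: float = 0.5e-6   # m, total pull displacement
    min_r2_on: float = 0.95
    max_start_height: float = 1e-6     # m, pre-detached bead guard


@dataclass
class StokesCalibration:
    """One bead's SFC result: fitted force profile plus diagnostics."""

    params: AcousticForceParams
    r2_on: float
    r2_off: float | None = None
    fitted_density: float | None = None   # kg/m^3, control analysis
    x: float = 0.0                        # um, bead position in FoV
    y: float = 0.0                        # um
    amplitude_pct: float = 0.0
    qc_pass: bool = True
    qc_reason: str = ""
    converged: bool = True

    def force_at(self, z: float = 1e-6) -> float:
        """Force [pN] of the fitted profile at height ``z`` [m] (default 1 um)."""
        return acoustic_force(z, self.params) * 1e12


def _r2(measured: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((measured - predicted) ** 2))
    ss_tot = float(np.sum((measured - np.mean(measured)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def fit_force_model(
    traj_on: Trajectory,
    bead: BeadSpec,
    fluid: FluidState,
    drag: WallDragSpec,
    qc: QCRules = QCRules(),
    phi_starts: tuple[float, ...] = (0.2, 0.8, 1.4),
) -> StokesCalibration:
    """Fit (f0, k_p, phi_p) to a force-on pull trace.

    Minimizes sum (z_num(t) - z_meas(t))^2 where z_num integrates the
    overdamped equation of motion from the measured start height.  The
    sine's periodicity creates local minima in phi_p, so the fit is
    multi-started over ``phi_starts`` and the best solution kept.
    """
    z = traj_on.z
    displacement = float(np.max(z) - np.min(z))
    if displacement < qc.min_displacement:
        return _rejected(traj_on, f"stuck bead: displacement {displacement*1e6:.3f} um")
    if z[0] > qc.max_start_height:
        return _rejected(traj_on, f"start height {z[0]*1e6:.2f} um above threshold")

    t = traj_on.time
    # The start height enters the stiff near-wall dynamics strongly but the
    # first sample carries tracking noise, so z0 is a bounded nuisance
    # parameter rather than being read off the trace.
    z0_obs = max(float(z[0]), 1e-8)
    # scale-free initial guesses: k_p from a quarter wave over the rise
    z_span = max(displacement, 1e-7)
    k0 = 0.25 * math.pi / (z_span * 1e6)

    def predict(theta: np.ndarray) -> np.ndarray:
        f0, k_p, phi_p, z0 = theta
        params = AcousticForceParams(f0=max(f0, 0.0), k_p=max(k_p, 1e-6), phi_p=phi_p % math.pi)
        return integrate_motion(params, bead, fluid, drag, z0, t).z

    def resid(theta: np.ndarray) -> np.ndarray:
        return (predict(theta) - z) * 1e6   # um-scale residuals

    best = None
    for phi0 in phi_starts:
        x0 = np.array([200.0, k0, phi0, z0_obs])
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=(
                    [0.0, 1e-4, 0.0, 1e-8],
                    [1e5, 10.0, math.pi - 1e-9, max(2.0 * z0_obs, 2e-6)],
                ),
                x_scale=[100.0, 0.05, 0.5, 0.1e-6],
                # FD steps must dominate the adaptive integrator's noise floor
                diff_step=1e-4,
                xtol=1e-12,
                ftol=1e-12,
            )
        except RuntimeError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return _rejected(traj_on, "optimizer failed on all starts")

    f0, k_p, phi_p, _z0_fit = best.x
    params = AcousticForceParams(
        f0=float(f0), k_p=float(k_p), phi_p=float(phi_p % math.pi),
        correction_method=str(drag.method.value),
    )
    r2_on = _r2(z, predict(best.x))
    calib = StokesCalibration(
        params=params,
        r2_on=r2_on,
        x=float(traj_on.x[0]) if traj_on.x is not None else 0.0,
        y=float(traj_on.y[0]) if traj_on.y is not None else 0.0,
        amplitude_pct=float(traj_on.amplitude[0]) if traj_on.amplitude is not None else 0.0,
        converged=bool(best.success),
    )
    if r2_on < qc.min_r2_on:
        calib.qc_pass = False
        calib.qc_reason = f"r2_on {r2_on:.4f} below {qc.min_r2_on}"
    return calib


def _rejected(traj: Trajectory, reason: str) -> StokesCalibration:
    return StokesCalibration(
        params=AcousticForceParams(f0=0.0, k_p=1e-3, phi_p=0.0),
        r2_on=-math.inf,
        qc_pass=False,
        qc_reason=reason,
        converged=False,
    )


def validate_fall(
    calib: StokesCalibration,
    traj_off: Trajectory,
    bead: BeadSpec,
    fluid: FluidState,
    drag: WallDragSpec,
    start_tolerance: float = 0.5e-6,
) -> float:
    """Parameter-free fall validation: R^2 of the gravity-only prediction.

    Nothing is fitted here — the fall is predicted from the known
    buoyancy-corrected weight and the chosen drag model, starting at the
    measured release height.
    """
    z0 = float(traj_off.z[0])
    predicted = simulate_fall(z0, bead, fluid, drag, traj_off.time - traj_off.time[0]).z
    r2 = _r2(traj_off.z, predicted)
    calib.r2_off = r2
    return r2


def fit_bead_density(
    traj_off: Trajectory,
    bead: BeadSpec,
    fluid: FluidState,
    drag: WallDragSpec,
) -> float:
    """Control analysis: fit the bead density [kg/m^3] to a fall trace.

    With the correct wall correction the recovered density should match
    the literature value for the bead material; a mismatched correction
    biases it.
    """
    t = traj_off.time - traj_off.time[0]
    z0 = float(traj_off.z[0])

    def resid(rho: np.ndarray) -> np.ndarray:
        trial = BeadSpec(radius=bead.radius, density=float(rho[0]), coating=bead.coating)
        return (simulate_fall(z0, trial, fluid, drag, t).z - traj_off.z) * 1e6

    sol = least_squares(resid, np.array([bead.density]),
                        bounds=([fluid.density_corrected + 0.1], [5000.0]))
    return float(sol.x[0])


def conversion_factor(points: list[tuple[float, float]], allow_single: bool = False) -> float:
    """Conversion factor c [pN/%^2] from (amplitude %, force pN) pairs.

    Single-parameter least squares of F = c V^2 through the origin; the
    forces are the fitted profiles evaluated at the 1 um reference height.
    Requires at least two points at non-zero amplitude unless
    ``allow_single`` forces the degenerate exact solution c = F / V^2.
    """
    pts = [(v, f) for v, f in points if v != 0.0]
    if len(pts) < 2 and not (allow_single and pts):
        raise ValueError("need at least two non-zero-amplitude force values")
    v = np.array([p[0] for p in pts], dtype=float)
    f = np.array([p[1] for p in pts], dtype=float)
    c = float(np.sum(f * v**2) / np.sum(v**4))
    if c <= 0:
        raise ValueError(f"non-positive conversion factor c = {c:.4g}; QC rejection")
    return c


@dataclass
class ConversionMap:
    """Spatially resolved amplitude^2 -> force conversion over the FoV."""

    x: np.ndarray                        # um
    y: np.ndarray                        # um
    c: np.ndarray                        # pN / %^2
    n_merged: np.ndarray | None = None   # beads merged into each point
    merge_radius: float = 5.0            # um
    interpolation: str = "linear"        # or "nearest"
    n_raw: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.x.size == 0:
            raise ValueError("conversion map has no points")
        if np.any(self.c <= 0):
            raise ValueError("all conversion factors must be positive")
        if self.n_merged is None:
            self.n_merged = np.ones_like(self.c)
        pts = np.column_stack([self.x, self.y])
        self._nearest = NearestNDInterpolator(pts, self.c)
        self._linear = None
        if self.interpolation == "linear" and self.x.size >= 3:
            try:
                self._linear = LinearNDInterpolator(pts, self.c)
            except QhullError:
                self._linear = None   # degenerate geometry: nearest fallback

    def lookup(self, x: np.ndarray | float, y: np.ndarray | float) -> np.ndarray | float:
        """Interpolated c at (x, y) [um]; nearest-neighbor outside the hull."""
        scalar = np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self._linear is not None:
            c = self._linear(x, y)
            outside = np.isnan(c)
            if np.any(outside):
                warnings.warn(
                    f"{int(outside.sum())} lookup point(s) outside the calibrated "
                    "hull; falling back to nearest neighbor",
                    stacklevel=2,
                )
                c[outside] = self._nearest(x[outside], y[outside])
        else:
            c = self._nearest(x, y)
        return float(c[0]) if scalar else c


def lookup_conversion(conv_map: ConversionMap, x: float, y: float) -> float:
    return conv_map.lookup(x, y)


def build_spatial_map(
    calibs: list[StokesCalibration],
    conversion_factors: list[float] | None = None,
    merge_radius: float = 5.0,
    interpolation: str = "linear",
) -> ConversionMap:
    """Build the spatial conversion map from QC-passing calibrations.

    ``conversion_factors`` gives c per calibration; if omitted it is taken
    as force-at-1um / amplitude^2 of each bead's single profile.  Beads
    closer than ``merge_radius`` are merged by averaging position and c
    (greedy, in input order).  Raises if nothing passes QC.
    """
    passing = [cal for cal in calibs if cal.qc_pass]
    if not passing:
        raise ValueError("no calibration passed QC; cannot build map")
    if conversion_factors is None:
        cs = [cal.force_at(1e-6) / cal.amplitude_pct**2 for cal in passing]
    else:
        cs = [c for cal, c in zip(calibs, conversion_factors) if cal.qc_pass]

    xs = np.array([cal.x for cal in passing])
    ys = np.array([cal.y for cal in passing])
    cs = np.asarray(cs, dtype=float)

    merged_x, merged_y, merged_c, merged_n = [], [], [], []
    used = np.zeros(len(passing), dtype=bool)
    for i in range(len(passing)):
        if used[i]:
            continue
        d = np.hypot(xs - xs[i], ys - ys[i])
        group = (d <= merge_radius) & ~used
        used |= group
        merged_x.append(float(xs[group].mean()))
        merged_y.append(float(ys[group].mean()))
        merged_c.append(float(cs[group].mean()))
        merged_n.append(int(group.sum()))

    return ConversionMap(
        x=np.array(merged_x),
        y=np.array(merged_y),
        c=np.array(merged_c),
        n_merged=np.array(merged_n, dtype=float),
        merge_radius=merge_radius,
        interpolation=interpolation,
        n_raw=len(passing),
    )
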