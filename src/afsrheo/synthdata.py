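"""Seeded synthetic-data generators for every pipeline input.

Three generators emulate the raw data an AFS instrument would export, so
the full calibration -> map -> rheology -> model-fit pipeline runs and is
tested without any recordings:

* ``gen_calibration_trace`` — pull (force on, ~1 s) and fall (force off)
  segments of a calibration bead, integrated from the physical force model
  with wall-corrected drag, sampled at the camera rate with additive
  Gaussian tracking noise.
* ``gen_spatial_field`` — a smooth band-limited random conversion-factor
  field c(x, y) over the field of view, rescaled to a prescribed max/min
  dynamic range (default 6), plus sampled virtual bead positions.
* ``gen_mosc_experiment`` — bead-on-cell multi-oscillation responses whose
  per-frequency transfer function comes from a ground-truth GKV modulus
  through the same partially-immersed Stokes-Einstein geometry factor the
  estimator uses, with per-bead stiffness heterogeneity, drift, tracking
  noise and an optional stiffness time schedule (drug effect + wash-out).

All generators are pure functions of (arguments, seed): a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import FOV_UM, ConversionMap
from .fluidprops import FluidState
from .forcemodel import AcousticForceParams, BeadSpec, Trajectory, integrate_motion
from .hydrodynamics import WallDragSpec
from .rheology import (
    ImmersionGeometry,
    OscProtocol,
    amplitude_from_force,
    design_mosc_force,
    geometry_factor,
)
from .viscomodels import GKVParams, gkv_modulus

__all__ = [
    "SyntheticScenario",
    "StiffnessSchedule",
    "gen_calibration_trace",
    "gen_spatial_field",
    "gen_mosc_experiment",
]


@dataclass(frozen=True)
class StiffnessSchedule:
    """Piecewise-constant multiplicative G0 schedule (drug time course).

    ``breakpoints`` are times [s] at which the factor switches; ``factors``
    has one more entry than ``breakpoints``.  The default models a drug
    arriving at 1600 s halving the stiffness, washed out at 4300 s.
    """

    breakpoints: tuple[float, ...] = (1600.0, 4300.0)
    factors: tuple[float, ...] = (1.0, 0.5, 1.0)

    def __post_init__(self) -> None:
        if len(self.factors) != len(self.breakpoints) + 1:
            raise ValueError("need one factor per interval (breakpoints + 1)")
        if any(f <= 0 for f in self.factors):
            raise ValueError("stiffness factors must be positive")

    def factor_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.breakpoints), t, side="right")
        return np.asarray(self.factors, dtype=float)[idx]


@dataclass(frozen=True)
class SyntheticScenario:
    """Noise/size parameters shared by the generators."""

    seed: int = 0
    noise_z: float = 20e-9        # m RMS tracking noise
    drift_rate: float = 0.2e-9    # m/s linear baseline drift
    n_beads: int = 15             # beads per experiment
    duration: float = 3700.0      # s
    bead_g0_cv: float = 0.10      # log-normal CV of per-bead G0
    stiffness_schedule: StiffnessSchedule | None = None

    def __post_init__(self) -> None:
        if self.noise_z < 0 or self.n_beads < 1 or self.duration <= 0:
            raise ValueError("invalid scenario parameters")


def gen_calibration_trace(
    params: AcousticForceParams,
    bead: BeadSpec,
    fluid: FluidState,
    drag: WallDragSpec,
    scenario: SyntheticScenario,
    amplitude_pct: float = 4.0,
    pull_duration: float = 1.0,
    fall_duration: float = 6.0,
    sampling_rate: float = 59.0,
    z_start: float = 0.1e-6,
    x_um: float = 0.0,
    y_um: float = 0.0,
    bead_id: str = "bead0",
) -> tuple[Trajectory, Trajectory]:
    """One SFC cycle: (pull trace, fall trace) with tracking noise.

    The pull phase applies ``params`` for ``pull_duration`` seconds from
    ``z_start``; the fall phase starts at the last pull position with the
    drive off.  The amplitude channel records ``amplitude_pct`` during the
    pull and 0 during the fall.
    """
    rng = np.random.default_rng(scenario.seed)
    t_on = np.arange(int(round(pull_duration * sampling_rate))) / sampling_rate
    t_off = np.arange(int(round(fall_duration * sampling_rate))) / sampling_rate

    clean_on = integrate_motion(params, bead, fluid, drag, z_start, t_on)
    clean_off = integrate_motion(None, bead, fluid, drag, float(clean_on.z[-1]), t_off)

    def noisy(z: np.ndarray) -> np.ndarray:
        return np.clip(z + rng.normal(0.0, scenario.noise_z, z.shape), 0.0, None)

    common = dict(temperature=fluid.temperature, bead_id=bead_id)
    traj_on = Trajectory(
        time=t_on,
        z=noisy(clean_on.z) if scenario.noise_z > 0 else clean_on.z,
        x=np.full_like(t_on, x_um),
        y=np.full_like(t_on, y_um),
        amplitude=np.full_like(t_on, amplitude_pct),
        phase=np.array(["on"] * t_on.size),
        **common,
    )
    traj_off = Trajectory(
        time=t_off + pull_duration,
        z=noisy(clean_off.z) if scenario.noise_z > 0 else clean_off.z,
        x=np.full_like(t_off, x_um),
        y=np.full_like(t_off, y_um),
        amplitude=np.zeros_like(t_off),
        phase=np.array(["off"] * t_off.size),
        **common,
    )
    return traj_on, traj_off


def gen_spatial_field(
    scenario: SyntheticScenario,
    extent_um: tuple[float, float] = FOV_UM,
    n_points: int = 1000,
    n_modes: int = 6,
    dynamic_range: float = 6.0,
    c_min: float = 0.3,
) -> tuple[callable, ConversionMap]:
    """Smooth random conversion-factor field and a sampled map.

    The field is a sum of ``n_modes`` random long-wavelength cosine modes,
    rescaled so max/min over the FoV equals ``dynamic_range`` exactly (with
    minimum ``c_min`` pN/%^2).  Returns ``(field(x, y), map)`` where the map
    holds the field sampled at ``n_points`` random bead positions.
    """
    if dynamic_range < 1.0:
        raise ValueError("dynamic range must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    lx, ly = extent_um
    kx = rng.uniform(0.5, 2.0, n_modes) * math.pi / lx * rng.choice([-1, 1], n_modes)
    ky = rng.uniform(0.5, 2.0, n_modes) * math.pi / ly * rng.choice([-1, 1], n_modes)
    phases = rng.uniform(0.0, 2.0 * math.pi, n_modes)
    amps = rng.uniform(0.5, 1.0, n_modes)

    def raw(x, y):
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        return np.sum(amps * np.cos(kx * x + ky * y + phases), axis=-1)

    # normalize on a fine grid so the prescribed range is exact on the FoV
    gx, gy = np.meshgrid(np.linspace(0, lx, 120), np.linspace(0, ly, 120))
    vals = raw(gx.ravel(), gy.ravel())
    lo, hi = float(vals.min()), float(vals.max())
    c_max = c_min * dynamic_range

    def field(x, y):
        if hi == lo:
            return np.full(np.shape(np.asarray(x)), c_min)
        u = (raw(x, y) - lo) / (hi - lo)
        return c_min + (c_max - c_min) * u

    xs = rng.uniform(0.0, lx, n_points)
    ys = rng.uniform(0.0, ly, n_points)
    conv_map = ConversionMap(x=xs, y=ys, c=field(xs, ys), n_raw=n_points)
    return field, conv_map


def gen_mosc_experiment(
    truth: GKVParams,
    protocol: OscProtocol,
    geom: ImmersionGeometry,
    scenario: SyntheticScenario,
    conv_map: ConversionMap | None = None,
) -> tuple[list[Trajectory], ConversionMap, np.ndarray]:
    """Synthetic bead-on-cell mOsc experiment.

    For each bead the linear response at each drive frequency is

        z_i(t) = Re[ F_i e^{i w_i t} / (6 pi R f(theta) G*(w_i, t)) ],

    the inverse of the estimator's relation, summed over components and
    superposed on a baseline, linear drift and Gaussian tracking noise.
    Per-bead moduli vary log-normally around ``truth`` (CV
    ``scenario.bead_g0_cv``); an optional stiffness schedule scales G0 over
    time (slow compared to the drive, applied adiabatically).

    Returns ``(trajectories, conversion map, force_pn)`` where the force
    waveform is also encoded in each trajectory's amplitude channel via the
    map (F = c V^2), exactly as the instrument would drive it.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration * protocol.sampling_rate))
    t = np.arange(n) / protocol.sampling_rate
    _, force_pn = design_mosc_force(protocol, t)
    gfac = geometry_factor(geom)
    omegas = 2.0 * math.pi * np.asarray(protocol.frequencies)

    if conv_map is None:
        conv_map = ConversionMap(
            x=np.array([0.0, FOV_UM[0], 0.0, FOV_UM[0]]),
            y=np.array([0.0, 0.0, FOV_UM[1], FOV_UM[1]]),
            c=np.full(4, 1.5),
        )

    sched = scenario.stiffness_schedule
    factor_t = sched.factor_at(t) if sched is not None else np.ones_like(t)

    # complex force amplitudes: F(t) = offset + sum A_i sin(w_i t)
    #   A sin(wt) = Re[-i A e^{iwt}] -> F_hat_i = -i A_i
    f_hat = -1j * np.asarray(protocol.amplitudes) * 1e-12   # N

    trajectories: list[Trajectory] = []
    for b in range(scenario.n_beads):
        sigma_ln = math.sqrt(math.log(1.0 + scenario.bead_g0_cv**2))
        g0_b = truth.G0 * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
        x0 = rng.uniform(0.05 * FOV_UM[0], 0.95 * FOV_UM[0])
        y0 = rng.uniform(0.05 * FOV_UM[1], 0.95 * FOV_UM[1])

        z = np.full(n, 0.2e-6)  # resting height of the tracked bead center
        for w, fh in zip(omegas, f_hat):
            g_star = gkv_modulus(w, GKVParams(G0=g0_b, alpha=truth.alpha,
                                              beta=truth.beta, t0=truth.t0))
            # adiabatic stiffness schedule: scale modulus per sample
            resp = fh / (gfac * g_star * factor_t)
            z = z + (resp * np.exp(1j * w * t)).real
        z = z + scenario.drift_rate * t
        if scenario.noise_z > 0:
            z = z + rng.normal(0.0, scenario.noise_z, n)
        z = np.clip(z, 0.0, None)

        c_here = conv_map.lookup(x0, y0)
        amplitude = amplitude_from_force(force_pn, c_here)
        trajectories.append(
            Trajectory(
                time=t,
                z=z,
                bead_id=f"bead{b}",
                x=np.full(n, x0),
                y=np.full(n, y0),
                amplitude=amplitude,
                temperature=36.0,
            )
        )
    return trajectories, conv_map, force_pn
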