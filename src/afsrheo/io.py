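"""File formats and configuration for the AFS workflow.

Everything on disk is delimited text with explicit unit suffixes in the
column names:

* trajectories: ``bead_id, t_s, x_um, y_um, z_um, amplitude_pct, phase``
* conversion maps: ``x_um, y_um, c_pN_per_pct2, n_merged``
* modulus spectra: ``t_center_s, freq_hz, G1_Pa, G2_Pa, G1_sem_Pa,
  G2_sem_Pa, absG_Pa, absG_err_Pa, delta_rad, delta_err_rad, n_beads,
  independent_flag``
* model fits: ``t_center_s, G0_Pa, alpha, beta, fx_Hz, E_Pa, r2,
  G0_ci2s, alpha_ci2s, beta_ci2s, fx_ci2s, n_beads, flag``

Configuration is YAML with fixed sections (fluid, bead, channel,
calibration, protocol, fitting, synthetic); unknown keys are rejected
before any computation.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import ConversionMap
from .fluidprops import ChannelGeometry, FluidState
from .forcemodel import BeadSpec, Trajectory
from .hydrodynamics import WallDragSpec
from .rheology import ImmersionGeometry, ModulusSpectrumSeries, OscProtocol

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_conversion_map",
    "write_conversion_map",
    "write_spectra",
    "read_spectra",
    "write_fits",
    "load_config",
    "RunConfig",
]

_TRAJ_COLUMNS = ["bead_id", "t_s", "x_um", "y_um", "z_um", "amplitude_pct", "phase"]


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a trajectory table; one file may hold many beads.

    Units are converted to SI internally.  Rows with non-finite z are
    dropped with a report; non-monotone time within a bead is an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = ~np.isfinite(df["z_um"])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()   # +2: header + 1-based
        print(f"{path}: dropped {bad.sum()} row(s) with non-finite z (lines {lines[:10]})")
        df = df[~bad]
    trajectories = []
    for bead_id, sub in df.groupby("bead_id", sort=False):
        t = sub["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-monotone time for bead {bead_id}")
        trajectories.append(
            Trajectory(
                time=t,
                z=sub["z_um"].to_numpy(float) * 1e-6,
                bead_id=str(bead_id),
                x=sub["x_um"].to_numpy(float),
                y=sub["y_um"].to_numpy(float),
                amplitude=sub["amplitude_pct"].to_numpy(float)
                if "amplitude_pct" in sub else None,
                phase=sub["phase"].to_numpy() if "phase" in sub else None,
            )
        )
    return trajectories


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    frames = []
    for tr in trajectories:
        n = tr.time.size
        frames.append(pd.DataFrame({
            "bead_id": np.full(n, tr.bead_id),
            "t_s": tr.time,
            "x_um": tr.x if tr.x is not None else np.zeros(n),
            "y_um": tr.y if tr.y is not None else np.zeros(n),
            "z_um": tr.z * 1e6,
            "amplitude_pct": tr.amplitude if tr.amplitude is not None else np.zeros(n),
            "phase": tr.phase if tr.phase is not None else np.full(n, ""),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_conversion_map(conv_map: ConversionMap, path: str | Path) -> None:
    pd.DataFrame({
        "x_um": conv_map.x,
        "y_um": conv_map.y,
        "c_pN_per_pct2": conv_map.c,
        "n_merged": conv_map.n_merged,
    }).to_csv(path, index=False)


def read_conversion_map(path: str | Path, interpolation: str = "linear") -> ConversionMap:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "c_pN_per_pct2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return ConversionMap(
        x=df["x_um"].to_numpy(float),
        y=df["y_um"].to_numpy(float),
        c=df["c_pN_per_pct2"].to_numpy(float),
        n_merged=df["n_merged"].to_numpy(float) if "n_merged" in df else None,
        interpolation=interpolation,
    )


def write_spectra(series: ModulusSpectrumSeries, path: str | Path) -> None:
    rows = []
    for j, tc in enumerate(series.window_centers):
        for k, f in enumerate(series.frequencies):
            rows.append({
                "t_center_s": tc,
                "freq_hz": f,
                "G1_Pa": series.g_storage[j, k],
                "G2_Pa": series.g_loss[j, k],
                "G1_sem_Pa": series.g_storage_sem[j, k],
                "G2_sem_Pa": series.g_loss_sem[j, k],
                "absG_Pa": series.g_abs[j, k],
                "absG_err_Pa": series.g_abs_err[j, k],
                "delta_rad": series.delta[j, k],
                "delta_err_rad": series.delta_err[j, k],
                "n_beads": int(series.n_beads_used[j, k]),
                "independent_flag": bool(series.independent[j]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectra(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fits(rows: list[dict], path: str | Path) -> None:
    cols = ["t_center_s", "G0_Pa", "alpha", "beta", "fx_Hz", "E_Pa", "r2",
            "G0_ci2s", "alpha_ci2s", "beta_ci2s", "fx_ci2s", "n_beads", "flag"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


_CONFIG_SECTIONS = {
    "fluid": {"temperature_C", "pressure_kPa", "viscosity_factor", "medium_label"},
    "bead": {"radius_um", "density_kg_m3", "coating"},
    "channel": {"height_um", "width_mm", "flow_ul_per_min"},
    "calibration": {"correction", "n_terms", "merge_radius_um", "z_reference_um",
                    "min_displacement_um", "min_r2_on", "max_start_height_um"},
    "protocol": {"frequencies_hz", "amplitudes_pn", "offset_pn", "duration_s",
                 "sampling_rate_hz", "window_s", "shift_s"},
    "geometry": {"theta_deg", "contact_diameter_um"},
    "fitting": {"model", "r2_floor", "n_boot", "log_residuals", "poisson_ratio"},
    "synthetic": {"noise_z_nm", "drift_nm_per_s", "n_beads", "duration_s",
                  "g0_pa", "alpha", "beta", "bead_g0_cv",
                  "schedule_breakpoints_s", "schedule_factors"},
    "seed": None,
    "output_dir": None,
    "log_level": None,
}


class RunConfig(dict):
    """Validated configuration mapping; behaves as a plain nested dict."""

    @property
    def fluid(self) -> FluidState:
        sec = self.get("fluid", {})
        return FluidState(
            temperature=sec.get("temperature_C", 36.0),
            ambient_pressure=sec.get("pressure_kPa", 101.325),
            viscosity_factor=sec.get("viscosity_factor", 1.0),
            medium_label=sec.get("medium_label", "water"),
        )

    @property
    def bead(self) -> BeadSpec:
        sec = self.get("bead", {})
        return BeadSpec(
            radius=sec.get("radius_um", 5.0) * 1e-6,
            density=sec.get("density_kg_m3", 1050.0),
            coating=sec.get("coating", ""),
        )

    @property
    def channel(self) -> ChannelGeometry:
        sec = self.get("channel", {})
        return ChannelGeometry(
            height=sec.get("height_um", 100.0) * 1e-6,
            width=sec.get("width_mm", 2.0) * 1e-3,
            flow_rate=sec.get("flow_ul_per_min", 0.0) * 1e-9 / 60.0,
        )

    @property
    def drag(self) -> WallDragSpec:
        sec = self.get("calibration", {})
        return WallDragSpec(
            method=sec.get("correction", "brenner"),
            bead_radius=self.bead.radius,
            n_terms=sec.get("n_terms", 100),
        )

    @property
    def protocol(self) -> OscProtocol:
        sec = self.get("protocol", {})
        return OscProtocol(
            frequencies=tuple(sec.get("frequencies_hz", (0.1, 0.5, 1.5))),
            amplitudes=tuple(sec.get("amplitudes_pn", (50.0, 50.0, 50.0))),
            offset=sec.get("offset_pn", 200.0),
            duration=sec.get("duration_s", 3700.0),
            sampling_rate=sec.get("sampling_rate_hz", 59.0),
            window=sec.get("window_s", 500.0),
            shift=sec.get("shift_s", 100.0),
        )

    @property
    def geometry(self) -> ImmersionGeometry:
        sec = self.get("geometry", {})
        if "contact_diameter_um" in sec:
            from .rheology import immersion_half_angle
            theta = immersion_half_angle(sec["contact_diameter_um"] * 1e-6, self.bead.radius)
        else:
            theta = math.radians(sec.get("theta_deg", 28.73))
        return ImmersionGeometry(bead_radius=self.bead.radius, theta=theta)

    @property
    def seed(self) -> int:
        return int(self.get("seed", 0))


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for section, keys in raw.items():
        if section not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown config section '{section}'")
        allowed = _CONFIG_SECTIONS[section]
        if allowed is not None and isinstance(keys, dict):
            unknown = set(keys) - allowed
            if unknown:
                raise ValueError(f"unknown key(s) {sorted(unknown)} in section '{section}'")
    return RunConfig(raw)
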