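"""Multi-oscillation microrheology: force design, demodulation, G*(omega).

A multi-frequency oscillatory (mOsc) force — several superimposed sinusoids
(default 0.1, 0.5 and 1.5 Hz) on a constant offset — is applied to a bead
partially immersed in the cell surface.  Within sliding time windows
(default 500 s length, 100 s shift) the complex amplitudes of force and
z-position at each drive frequency are extracted and the complex shear
modulus follows from the partially-immersed generalized Stokes-Einstein
relation

    G*(omega) = F~(omega) / (6 pi R f(theta) z~(omega)),

where theta is the immersion half-angle of the bead-cell contact circle
(theta = arcsin(d / 2R)) and f(theta) the immersion correction with
f(90 deg) = 1, recovering the classical relation for a fully immersed bead.

Demodulation is implemented as harmonic regression: ordinary least squares
of the windowed signal on [1, t, cos(w_i t), sin(w_i t)].  On windows that
hold an integer number of cycles of every drive frequency the regressors
are exactly orthogonal, so the estimate is leakage-free and exact for
noiseless drive-bin signals while absorbing offset and linear drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import ConversionMap
from .forcemodel import Trajectory

__all__ = [
    "OscProtocol",
    "ImmersionGeometry",
    "ModulusSpectrumSeries",
    "design_mosc_force",
    "amplitude_from_force",
    "reconstruct_force",
    "immersion_half_angle",
    "immersion_correction",
    "geometry_factor",
    "estimate_modulus_window",
    "sliding_window_series",
    "aggregate_beads",
    "THETA_DEFAULT_DEG",
]

THETA_DEFAULT_DEG = 28.73   # population mean immersion half-angle


@dataclass(frozen=True)
class OscProtocol:
    """mOsc drive protocol and windowing parameters.

    Defaults follow the instrument protocol: components at 0.1/0.5/1.5 Hz
    sampled at 59 Hz, analyzed in 500 s windows shifted by 100 s — every
    window holds exactly 50/250/750 cycles, so demodulation is leakage-free.
    """

    frequencies: tuple[float, ...] = (0.1, 0.5, 1.5)   # Hz
    amplitudes: tuple[float, ...] = (50.0, 50.0, 50.0)  # pN per component
    offset: float = 200.0          # pN
    duration: float = 3700.0       # s
    sampling_rate: float = 59.0    # Hz
    window: float = 500.0          # s, Delta t
    shift: float = 100.0           # s, Delta t_sh

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.amplitudes):
            raise ValueError("one amplitude per component frequency required")
        if any(f <= 0 for f in self.frequencies) or any(a < 0 for a in self.amplitudes):
            raise ValueError("frequencies must be positive, amplitudes non-negative")
        for f in self.frequencies:
            cycles = f * self.window
            if abs(cycles - round(cycles)) > 1e-9:
                raise ValueError(
                    f"window of {self.window} s holds a non-integer number of "
                    f"cycles ({cycles}) of the {f} Hz component"
                )
        if self.sampling_rate <= 2.0 * max(self.frequencies):
            raise ValueError("sampling rate must exceed twice the highest frequency")
        if self.offset < sum(self.amplitudes):
            raise ValueError(
                f"force could go negative: offset must be >= sum of component "
                f"amplitudes ({sum(self.amplitudes)} pN)"
            )


@dataclass(frozen=True)
class ImmersionGeometry:
    """Bead-cell contact geometry for the modulus geometry factor."""

    bead_radius: float = 5e-6                     # m
    theta: float = math.radians(THETA_DEFAULT_DEG)  # rad

    def __post_init__(self) -> None:
        if self.bead_radius <= 0:
            raise ValueError("bead radius must be positive")
        if not 0.0 < self.theta <= math.pi / 2:
            raise ValueError("theta must lie in (0, 90] degrees")

    @property
    def correction(self) -> float:
        return immersion_correction(self.theta)


def immersion_half_angle(d: float, R: float) -> float:
    """Immersion half-angle theta = arcsin(d / 2R) [rad].

    ``d`` is the diameter of the bead-cell contact circle, ``R`` the bead
    radius; the contact circle is a chord circle of the sphere.
    """
    if d <= 0:
        raise ValueError("contact diameter must be positive")
    if d > 2.0 * R:
        raise ValueError("contact diameter cannot exceed the bead diameter")
    return math.asin(d / (2.0 * R))


def immersion_correction(theta: float) -> float:
    """Immersion factor f(theta), dimensionless, on theta in (0, 90] deg.

    Implemented as the normalized immersion depth of the contact cap,
    f(theta) = 1 - cos(theta): smooth, strictly increasing, below 1 for
    partial immersion and exactly 1 at theta = 90 deg so that the modulus
    estimate reduces to the generalized Stokes-Einstein relation.
    """
    if not 0.0 < theta <= math.pi / 2:
        raise ValueError("theta must lie in (0, 90] degrees")
    return 1.0 - math.cos(theta)


def geometry_factor(geom: ImmersionGeometry) -> float:
    """g = 6 pi R f(theta) [m]; G* = F~ / (g z~)."""
    return 6.0 * math.pi * geom.bead_radius * geom.correction


def design_mosc_force(protocol: OscProtocol, t: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sampled mOsc force waveform (t [s], F [pN]).

    F(t) = offset + sum_i A_i sin(2 pi f_i t), guaranteed non-negative by the
    protocol invariant offset >= sum(A_i).
    """
    if t is None:
        n = int(round(protocol.duration * protocol.sampling_rate))
        t = np.arange(n) / protocol.sampling_rate
    else:
        t = np.asarray(t, dtype=float)
    f = np.full_like(t, protocol.offset)
    for freq, amp in zip(protocol.frequencies, protocol.amplitudes):
        f += amp * np.sin(2.0 * math.pi * freq * t)
    return t, f


def amplitude_from_force(force_pn: np.ndarray, c: float) -> np.ndarray:
    """Drive amplitude [%] producing force F = c V^2: V = sqrt(F / c)."""
    force_pn = np.asarray(force_pn, dtype=float)
    if c <= 0:
        raise ValueError("conversion factor must be positive")
    if np.any(force_pn < 0):
        raise ValueError("force must be non-negative to invert F = c V^2")
    return np.sqrt(force_pn / c)


def reconstruct_force(traj: Trajectory, conv_map: ConversionMap) -> np.ndarray:
    """Force [pN] per sample: F(t) = c(x(t), y(t)) * V(t)^2.

    The conversion factor is re-looked-up along the bead's lateral drift
    path so cell-motility-induced position changes are corrected for.
    """
    if traj.amplitude is None:
        raise ValueError("trajectory has no amplitude channel")
    if traj.x is None or traj.y is None:
        raise ValueError("trajectory has no lateral (x, y) coordinates")
    c = conv_map.lookup(traj.x, traj.y)
    return c * traj.amplitude**2


def _design_matrix(t: np.ndarray, freqs: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t), t - t.mean()]
    for f in freqs:
        w = 2.0 * math.pi * f
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def _demodulate(design_pinv: np.ndarray, signal: np.ndarray, n_freqs: int) -> np.ndarray:
    """Complex amplitudes Z_i (signal = Re[Z_i e^{i w_i t}]) at each drive bin."""
    coef = design_pinv @ signal
    cos_c = coef[2:2 + 2 * n_freqs:2]
    sin_c = coef[3:3 + 2 * n_freqs:2]
    return cos_c - 1j * sin_c


def estimate_modulus_window(
    t: np.ndarray,
    force_pn: np.ndarray,
    z_m: np.ndarray,
    freqs: tuple[float, ...],
    geom: ImmersionGeometry,
    z_floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency complex shear modulus G* [Pa] in one window.

    Returns ``(G, valid)`` where ``G`` is complex per frequency and
    ``valid`` flags bins whose position amplitude exceeds ``z_floor`` [m].
    Time, force and position must share one uniform grid covering an
    integer number of cycles of every frequency.
    """
    t = np.asarray(t, dtype=float)
    design = _design_matrix(t - t[0], tuple(freqs))
    pinv = np.linalg.pinv(design)
    f_hat = _demodulate(pinv, np.asarray(force_pn, float) * 1e-12, len(freqs))
    z_hat = _demodulate(pinv, np.asarray(z_m, float), len(freqs))
    valid = np.abs(z_hat) > z_floor
    g = np.full(len(freqs), np.nan + 0j)
    g[valid] = f_hat[valid] / (geometry_factor(geom) * z_hat[valid])
    return g, valid


@dataclass
class ModulusSpectrumSeries:
    """Windowed modulus spectra, per bead and aggregated across beads.

    ``g_complex`` has shape (n_beads, n_windows, n_freqs); aggregated
    fields are (n_windows, n_freqs).  Points violating passivity
    (G' < 0 or G'' < 0) are flagged in ``valid`` rather than dropped.
    """

    window_centers: np.ndarray          # s
    frequencies: np.ndarray             # Hz
    g_complex: np.ndarray               # complex, (beads, windows, freqs)
    valid: np.ndarray                   # bool, same shape
    independent: np.ndarray             # bool per window (non-overlapping set)
    bead_ids: list[str] = field(default_factory=list)

    # aggregated across beads (filled by aggregate_beads)
    g_storage: np.ndarray | None = None
    g_loss: np.ndarray | None = None
    g_storage_sem: np.ndarray | None = None
    g_loss_sem: np.ndarray | None = None
    g_abs: np.ndarray | None = None
    g_abs_err: np.ndarray | None = None
    delta: np.ndarray | None = None
    delta_err: np.ndarray | None = None
    n_beads_used: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return self.g_complex.shape[0]


def window_starts(duration: float, window: float, shift: float) -> np.ndarray:
    """Start times of all full-length sliding windows."""
    n = int(math.floor((duration - window) / shift)) + 1
    if n < 1:
        raise ValueError("trajectory shorter than one analysis window")
    return np.arange(n) * shift


def sliding_window_series(
    trajectories: list[Trajectory],
    conv_map: ConversionMap,
    protocol: OscProtocol,
    geom: ImmersionGeometry,
) -> ModulusSpectrumSeries:
    """Sliding-window modulus spectra for a set of beads.

    Windows of length ``protocol.window`` are advanced by ``protocol.shift``;
    incomplete trailing windows are dropped.  Windows spaced a multiple of
    the window length apart are marked independent (non-overlapping).
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    freqs = tuple(protocol.frequencies)
    duration = float(trajectories[0].time[-1] - trajectories[0].time[0])
    starts = window_starts(duration + 1.0 / protocol.sampling_rate, protocol.window, protocol.shift)
    centers = starts + protocol.window / 2.0
    n_per_win = int(round(protocol.window * protocol.sampling_rate))
    independent = np.isclose(
        np.mod(starts, protocol.window), 0.0
    )  # non-overlapping subset anchored at t = 0

    n_b, n_w, n_f = len(trajectories), len(starts), len(freqs)
    g = np.full((n_b, n_w, n_f), np.nan + 0j)
    valid = np.zeros((n_b, n_w, n_f), dtype=bool)

    # one shared design-matrix pseudo-inverse: all windows share the grid
    t_rel = np.arange(n_per_win) / protocol.sampling_rate
    pinv = np.linalg.pinv(_design_matrix(t_rel, freqs))
    gfac = geometry_factor(geom)

    for i, traj in enumerate(trajectories):
        force_pn = reconstruct_force(traj, conv_map)
        for j, start in enumerate(starts):
            k0 = int(round(start * protocol.sampling_rate))
            k1 = k0 + n_per_win
            if k1 > traj.z.size:
                continue
            f_hat = _demodulate(pinv, force_pn[k0:k1] * 1e-12, n_f)
            z_hat = _demodulate(pinv, traj.z[k0:k1], n_f)
            ok = np.abs(z_hat) > 1e-12
            g[i, j, ok] = f_hat[ok] / (gfac * z_hat[ok])
            # retain passive-material points: G' >= 0 and G'' >= 0
            ok = ok & (g[i, j].real >= 0) & (g[i, j].imag >= 0)
            valid[i, j] = ok
    series = ModulusSpectrumSeries(
        window_centers=centers,
        frequencies=np.asarray(freqs, float),
        g_complex=g,
        valid=valid,
        independent=independent,
        bead_ids=[tr.bead_id for tr in trajectories],
    )
    return aggregate_beads(series)


def aggregate_beads(series: ModulusSpectrumSeries) -> ModulusSpectrumSeries:
    """Aggregate per-bead spectra: mean and SEM of G'/G'' across beads.

    |G| and the phase delta are computed from the aggregated components,
    their errors by first-order propagation of the component SEMs.
    """
    import warnings as _warnings

    g = series.g_complex
    valid = series.valid
    n_used = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        gs = np.where(valid, g.real, np.nan)
        gl = np.where(valid, g.imag, np.nan)
        mean_s = np.nanmean(np.where(valid, gs, np.nan), axis=0)
        mean_l = np.nanmean(np.where(valid, gl, np.nan), axis=0)
        std_s = np.nanstd(np.where(valid, gs, np.nan), axis=0, ddof=1)
        std_l = np.nanstd(np.where(valid, gl, np.nan), axis=0, ddof=1)
        sem_s = std_s / np.sqrt(n_used)
        sem_l = std_l / np.sqrt(n_used)
        single = n_used == 1
        sem_s[single] = 0.0
        sem_l[single] = 0.0
        g_abs = np.hypot(mean_s, mean_l)
        delta = np.arctan2(mean_l, mean_s)
        # d|G| = (G' dG' + G'' dG'')/|G| ; ddelta = (G' dG'' - G'' dG')/|G|^2
        g_abs_err = np.sqrt((mean_s * sem_s) ** 2 + (mean_l * sem_l) ** 2) / g_abs
        delta_err = np.sqrt((mean_s * sem_l) ** 2 + (mean_l * sem_s) ** 2) / g_abs**2
    series.g_storage = mean_s
    series.g_loss = mean_l
    series.g_storage_sem = sem_s
    series.g_loss_sem = sem_l
    series.g_abs = g_abs
    series.g_abs_err = g_abs_err
    series.delta = delta
    series.delta_err = delta_err
    series.n_beads_used = n_used
    return series
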