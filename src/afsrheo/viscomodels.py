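"""Fractional viscoelastic models and spectrum fitting.

Two models describe the measured complex shear modulus G*(omega):

* SFE (single fractional element, "springpot"): G* = G_tilde (i omega t0)^a,
  a single power law applied separately to storage and loss moduli.
* GKV (generalized Kelvin-Voigt): two springpots in parallel,

      G*(omega) = G0 [ (i omega t0)^alpha + (i omega t0)^beta ],  t0 = 1 s,

  with three parameters (G0, alpha, beta).  Its storage and loss parts are

      G'  = G0 [ w^a cos(pi a/2) + w^b cos(pi b/2) ]
      G'' = G0 [ w^a sin(pi a/2) + w^b sin(pi b/2) ],   w = omega t0,

  which cross at a unique crossover frequency when alpha > 1/2 > beta.

The module also provides joint GKV fitting, separate SFE fitting, per-bead
bootstrap confidence intervals, and derived quantities (crossover frequency,
Young's modulus E = 2 G0 (1 + nu)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SFEParams",
    "GKVParams",
    "gkv_modulus",
    "sfe_modulus",
    "crossover_frequency",
    "fit_sfe_separate",
    "fit_gkv",
    "bootstrap_ci",
    "young_modulus",
    "generalized_maxwell",
]

T0_DEFAULT = 1.0  # s, reference time fixing the springpot units


@dataclass(frozen=True)
class SFEParams:
    """Single springpot: G* = prefactor * (i omega t0)^exponent."""

    prefactor: float            # Pa
    exponent: float             # in [0, 1]
    t0: float = T0_DEFAULT      # s
    applies_to: str = "complex"  # storage | loss | complex
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if not 0.0 <= self.exponent <= 1.0:
            raise ValueError("exponent must lie in [0, 1]")


@dataclass(frozen=True)
class GKVParams:
    """Generalized Kelvin-Voigt triple (G0, alpha, beta) with t0 = 1 s."""

    G0: float                   # Pa
    alpha: float
    beta: float
    t0: float = T0_DEFAULT      # s
    r2: float | None = None
    boot_ci: dict[str, float] | None = None   # 2-sigma half-widths per parameter
    n_boot: int = 0
    flag: str = ""

    def __post_init__(self) -> None:
        if self.G0 <= 0:
            raise ValueError("G0 must be positive")
        if not 0.0 <= self.beta <= self.alpha <= 1.0:
            raise ValueError("require 0 <= beta <= alpha <= 1")

    @property
    def crossover_hz(self) -> float | None:
        try:
            return crossover_frequency(self.alpha, self.beta)[1]
        except ValueError:
            return None


def gkv_modulus(omega: float | np.ndarray, p: GKVParams) -> complex | np.ndarray:
    """Complex GKV shear modulus [Pa] at angular frequency ``omega`` [rad/s]."""
    w = np.asarray(omega, dtype=float) * p.t0
    if np.any(w <= 0):
        raise ValueError("omega must be positive")
    iw = 1j * w
    g = p.G0 * (iw**p.alpha + iw**p.beta)
    return g if np.ndim(omega) else complex(g)


def sfe_modulus(omega: float | np.ndarray, p: SFEParams) -> complex | np.ndarray:
    """Complex springpot modulus [Pa] at ``omega`` [rad/s]."""
    w = np.asarray(omega, dtype=float) * p.t0
    if np.any(w <= 0):
        raise ValueError("omega must be positive")
    g = p.prefactor * (1j * w) ** p.exponent
    return g if np.ndim(omega) else complex(g)


def crossover_frequency(alpha: float, beta: float, t0: float = T0_DEFAULT) -> tuple[float, float]:
    """Angular and ordinary crossover frequency (omega_x [rad/s], f_x [Hz]).

    G' = G'' requires

        w^(a-b) = (cos(pi b/2) - sin(pi b/2)) / (sin(pi a/2) - cos(pi a/2)),

    which has a positive solution exactly when alpha > 1/2 > beta (one
    springpot solid-like, the other fluid-like).  Raises ``ValueError``
    with a reason when no crossover exists.
    """
    if not (0.0 <= beta <= 1.0 and 0.0 <= alpha <= 1.0):
        raise ValueError("exponents must lie in [0, 1]")
    if math.isclose(alpha, beta):
        raise ValueError("no crossover: alpha = beta (constant loss tangent)")
    a, b = max(alpha, beta), min(alpha, beta)
    num = math.cos(math.pi * b / 2.0) - math.sin(math.pi * b / 2.0)
    den = math.sin(math.pi * a / 2.0) - math.cos(math.pi * a / 2.0)
    if num <= 0 or den <= 0:
        raise ValueError(
            "no crossover: requires alpha > 1/2 > beta so that one element is "
            "solid-like and the other fluid-like"
        )
    w_x = (num / den) ** (1.0 / (a - b))
    omega_x = w_x / t0
    return omega_x, omega_x / (2.0 * math.pi)


def young_modulus(G0: float, nu: float = 0.5) -> float:
    """Young's modulus E = 2 G0 (1 + nu) [Pa] for Poisson ratio ``nu``."""
    if not -1.0 < nu <= 0.5:
        raise ValueError("Poisson ratio must lie in (-1, 0.5]")
    return 2.0 * G0 * (1.0 + nu)


def _r2(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def _fit_power_law(freqs: np.ndarray, g: np.ndarray, t0: float) -> tuple[float, float, float]:
    """LS fit of g = G_tilde * (2 pi f t0)^a on linear scale, log-log seeded."""
    w = 2.0 * math.pi * freqs * t0
    slope, logg = np.polyfit(np.log(w), np.log(g), 1)
    x0 = np.array([math.exp(logg), np.clip(slope, 0.0, 1.0)])

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * w ** p[1] - g

    sol = least_squares(resid, x0, bounds=([1e-12, 0.0], [np.inf, 1.0]))
    r2 = _r2(g, sol.x[0] * w ** sol.x[1])
    return float(sol.x[0]), float(sol.x[1]), r2


def fit_sfe_separate(
    freqs: np.ndarray,
    g_storage: np.ndarray,
    g_loss: np.ndarray,
    t0: float = T0_DEFAULT,
    r2_floor: float = 0.9,
) -> tuple[SFEParams, SFEParams]:
    """Independent power-law fits to G'(f) and G''(f).

    Non-positive moduli are excluded; fewer than 2 usable frequencies per
    component is an error.  Fits with R^2 below ``r2_floor`` are still
    returned (callers decide on retention); the floor matches the
    presentation cut used for reported parameters.
    """
    freqs = np.asarray(freqs, dtype=float)
    out = []
    for g, label in ((np.asarray(g_storage, float), "storage"), (np.asarray(g_loss, float), "loss")):
        keep = g > 0
        if np.count_nonzero(keep) < 2:
            raise ValueError(f"need >= 2 positive {label} moduli to fit a power law")
        pref, expo, r2 = _fit_power_law(freqs[keep], g[keep], t0)
        out.append(SFEParams(prefactor=pref, exponent=expo, t0=t0, applies_to=label, r2=r2))
    return out[0], out[1]


def fit_gkv(
    freqs: np.ndarray,
    g_storage: np.ndarray,
    g_loss: np.ndarray,
    weights: np.ndarray | None = None,
    t0: float = T0_DEFAULT,
    log_residuals: bool = False,
    r2_floor: float = 0.7,
) -> GKVParams:
    """Joint least-squares GKV fit to the concatenated (G', G'') vector.

    Bounds G0 > 0, alpha/beta in [0, 1]; the two springpots are symmetric so
    the result is reported with alpha >= beta.  ``weights`` (per frequency)
    multiply both components' residuals.  R^2 is computed over the
    concatenated vector; fits below ``r2_floor`` are flagged, not dropped.
    """
    freqs = np.asarray(freqs, dtype=float)
    gs = np.asarray(g_storage, dtype=float)
    gl = np.asarray(g_loss, dtype=float)
    if freqs.size < 2:
        raise ValueError("need >= 2 frequencies for a 3-parameter GKV fit")
    w = 2.0 * math.pi * freqs * t0
    y = np.concatenate([gs, gl])
    wt = np.ones_like(freqs) if weights is None else np.asarray(weights, dtype=float)
    wt2 = np.concatenate([wt, wt])

    def model(p: np.ndarray) -> np.ndarray:
        g0, a, b = p
        ca, sa = math.cos(math.pi * a / 2), math.sin(math.pi * a / 2)
        cb, sb = math.cos(math.pi * b / 2), math.sin(math.pi * b / 2)
        return np.concatenate([
            g0 * (w**a * ca + w**b * cb),
            g0 * (w**a * sa + w**b * sb),
        ])

    def resid(p: np.ndarray) -> np.ndarray:
        m = model(p)
        if log_residuals:
            return wt2 * (np.log(np.maximum(m, 1e-300)) - np.log(np.maximum(y, 1e-300)))
        return wt2 * (m - y)

    g0_init = max(float(np.median(gs)), 1e-9)
    best = None
    for a0, b0 in ((0.8, 0.05), (0.5, 0.2), (0.95, 0.4)):
        sol = least_squares(
            resid, np.array([g0_init, a0, b0]),
            bounds=([1e-12, 0.0, 0.0], [np.inf, 1.0, 1.0]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    g0, a, b = best.x
    if b > a:
        a, b = b, a
    r2 = _r2(y, model(np.array([g0, a, b])))
    flag = ""
    if not best.success:
        flag = "non-convergent"
    elif r2 < r2_floor:
        flag = f"r2<{r2_floor}"
    return GKVParams(G0=float(g0), alpha=float(a), beta=float(b), t0=t0, r2=r2, flag=flag)


def bootstrap_ci(
    freqs: np.ndarray,
    per_bead_storage: np.ndarray,
    per_bead_loss: np.ndarray,
    fit_fn=fit_gkv,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """2-sigma bootstrap CIs for fit parameters, resampling beads.

    ``per_bead_storage``/``per_bead_loss`` are (n_beads, n_freq) arrays.
    Each bootstrap sample resamples beads with replacement, averages the
    spectra and refits; the CI is twice the standard deviation of each
    parameter over the ``n_boot`` refits.  Requires >= 2 beads.
    """
    gs = np.atleast_2d(np.asarray(per_bead_storage, dtype=float))
    gl = np.atleast_2d(np.asarray(per_bead_loss, dtype=float))
    n_beads = gs.shape[0]
    if n_beads < 2:
        raise ValueError("bootstrap CI undefined for fewer than 2 beads")
    rng = np.random.default_rng(rng)
    samples: dict[str, list[float]] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n_beads, size=n_beads)
        fit = fit_fn(freqs, gs[idx].mean(axis=0), gl[idx].mean(axis=0))
        if isinstance(fit, GKVParams):
            vals = {"G0": fit.G0, "alpha": fit.alpha, "beta": fit.beta}
            try:
                vals["fx"] = crossover_frequency(fit.alpha, fit.beta, fit.t0)[1]
            except ValueError:
                pass
        else:  # pair of SFEParams from fit_sfe_separate-style callables
            store, loss = fit
            vals = {
                "prefactor_storage": store.prefactor,
                "exponent_storage": store.exponent,
                "prefactor_loss": loss.prefactor,
                "exponent_loss": loss.exponent,
            }
        for k, v in vals.items():
            samples.setdefault(k, []).append(v)
    return {k: 2.0 * float(np.std(v, ddof=0)) for k, v in samples.items()}


def generalized_maxwell(*args, **kwargs):
    """Placeholder for the generalized Maxwell fractional model."""
    raise NotImplementedError(
        "generalized Maxwell model is not implemented (supplementary-only form)"
    )
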