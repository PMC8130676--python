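"""Temperature- and pressure-dependent properties of the suspension medium.

The acoustic force calibration rests on knowing the viscosity and density of
the medium at the experiment temperature.  For water these are parameterized
by a fourth-order polynomial in temperature for the air-saturated density and
the isothermal compressibility, a modified Andrade equation for the dynamic
viscosity, and the Newton-Laplace relation for the speed of sound.  Culture
medium is treated as water with an optional multiplicative viscosity factor
(serum raises the viscosity by only a few percent).

All public functions take temperature in degrees Celsius and pressure in kPa
and return SI quantities.  The parameterizations are valid on 5-40 degC; the
0 degC endpoint is admitted with a warning because the polynomial constant
term is the 0 degC value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "FluidState",
    "ChannelGeometry",
    "water_density_air_saturated",
    "water_compressibility",
    "corrected_density",
    "water_viscosity",
    "speed_of_sound",
    "wall_shear_stress",
    "STANDARD_PRESSURE_KPA",
]

STANDARD_PRESSURE_KPA = 101.325

# Fourth-order polynomial constants (A + B*T + C*T^2 + D*T^3 + E*T^4),
# T in degC.  Density in kg/m^3, isothermal compressibility in 1/kPa.
_DENSITY_COEFFS = (999.84847, 6.337563e-2, -8.523829e-3, 6.943248e-5, -3.821216e-7)
_COMPRESSIBILITY_COEFFS = (50.83101e-8, -3.68293e-9, 7.263725e-11, -6.597702e-13, 2.87767e-15)

# Modified Andrade constants: eta[mPa*s] = exp(A_G + B_G / (C_G + T)).
_ANDRADE_A = -3.63148
_ANDRADE_B = 542.05   # degC
_ANDRADE_C = 129.0    # degC

_T_HARD_MIN, _T_SOFT_MIN, _T_MAX = 0.0, 5.0, 40.0


def _check_temperature(T: float) -> None:
    if not math.isfinite(T):
        raise ValueError("temperature must be finite")
    if T < _T_HARD_MIN or T > _T_MAX:
        raise ValueError(
            f"temperature {T} degC outside the supported range "
            f"[{_T_HARD_MIN}, {_T_MAX}] degC (parameterization valid on "
            f"[{_T_SOFT_MIN}, {_T_MAX}] degC)"
        )
    if T < _T_SOFT_MIN:
        warnings.warn(
            f"temperature {T} degC below the stated validity range "
            f"[{_T_SOFT_MIN}, {_T_MAX}] degC; extrapolating",
            stacklevel=3,
        )


def _poly4(coeffs: tuple[float, ...], T: float) -> float:
    a, b, c, d, e = coeffs
    return a + T * (b + T * (c + T * (d + T * e)))


def water_density_air_saturated(T: float) -> float:
    """Density of air-saturated water in kg/m^3 at temperature ``T`` [degC]."""
    _check_temperature(T)
    return _poly4(_DENSITY_COEFFS, T)


def water_compressibility(T: float) -> float:
    """Isothermal compressibility of water in 1/kPa at ``T`` [degC]."""
    _check_temperature(T)
    return _poly4(_COMPRESSIBILITY_COEFFS, T)


def corrected_density(T: float, P: float = STANDARD_PRESSURE_KPA) -> float:
    """Compressibility-corrected water density [kg/m^3].

    rho_m = rho_AS(T) * (1 + kappa(T) * (P - 101.325 kPa)), with P in kPa.
    At the reference pressure this is exactly the air-saturated density.
    """
    if P <= 0:
        raise ValueError("pressure must be positive")
    rho = water_density_air_saturated(T)
    kappa = water_compressibility(T)
    return rho * (1.0 + kappa * (P - STANDARD_PRESSURE_KPA))


def water_viscosity(T: float, viscosity_factor: float = 1.0) -> float:
    """Dynamic viscosity of water in Pa*s at ``T`` [degC].

    Modified Andrade form eta[mPa*s] = exp(A + B/(C + T)); the optional
    ``viscosity_factor`` scales the result for serum-containing media.
    """
    _check_temperature(T)
    eta_mpas = math.exp(_ANDRADE_A + _ANDRADE_B / (_ANDRADE_C + T))
    return eta_mpas * 1e-3 * viscosity_factor


def speed_of_sound(T: float, P: float = STANDARD_PRESSURE_KPA) -> float:
    """Speed of sound in water [m/s] from the Newton-Laplace equation.

    c = 1 / sqrt(kappa * rho) with kappa converted to 1/Pa.
    """
    kappa_per_pa = water_compressibility(T) * 1e-3  # 1/kPa -> 1/Pa
    rho = corrected_density(T, P)
    return 1.0 / math.sqrt(kappa_per_pa * rho)


@dataclass(frozen=True)
class FluidState:
    """Medium properties evaluated at a fixed temperature and pressure."""

    temperature: float                      # degC
    ambient_pressure: float = STANDARD_PRESSURE_KPA  # kPa
    viscosity_factor: float = 1.0           # multiplicative, for serum media
    medium_label: str = "water"

    density_air_saturated: float = field(init=False)  # kg/m^3
    compressibility: float = field(init=False)        # 1/kPa
    density_corrected: float = field(init=False)      # kg/m^3
    viscosity: float = field(init=False)              # Pa*s
    speed_of_sound: float = field(init=False)         # m/s

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "density_air_saturated", water_density_air_saturated(self.temperature)
        )
        object.__setattr__(
            self, "compressibility", water_compressibility(self.temperature)
        )
        object.__setattr__(
            self,
            "density_corrected",
            corrected_density(self.temperature, self.ambient_pressure),
        )
        object.__setattr__(
            self,
            "viscosity",
            water_viscosity(self.temperature, self.viscosity_factor),
        )
        object.__setattr__(
            self,
            "speed_of_sound",
            speed_of_sound(self.temperature, self.ambient_pressure),
        )


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular flow-chamber geometry (defaults: 100 um x 2 mm)."""

    height: float = 100e-6     # m
    width: float = 2e-3        # m
    flow_rate: float = 0.0     # m^3/s

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("channel height and width must be positive")
        if self.flow_rate < 0:
            raise ValueError("flow rate must be non-negative")


def wall_shear_stress(fluid: FluidState, channel: ChannelGeometry) -> float:
    """Wall shear stress [Pa] at the center of a rectangular channel.

    tau_w = 6 * mu * Q / (h^2 * w) for a wide, shallow chamber.
    """
    return 6.0 * fluid.viscosity * channel.flow_rate / (channel.height**2 * channel.width)
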