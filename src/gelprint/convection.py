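"""Natural-convection heat transfer via the Nusselt–Grashof–Prandtl correlation.

The extrusion barrel hangs vertically in still, chilled air, so heat leaves
its exposed surfaces by laminar natural convection.  The film coefficient
follows the classical correlation chain

    Gr = beta * g * dT * rho**2 * L**3 / mu**2
    Pr = cp * mu / k
    Nu = c * (Gr * Pr)**m          (c = 0.59, m = 1/4: vertical, laminar)
    h_c = Nu * k / L

with all air properties evaluated at the film temperature.  A small built-in
dry-air property table (1 atm, 250–350 K, linearly interpolated) supplies
the properties; beta is taken as 1/T_film (ideal gas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvectionError",
    "FluidProperties",
    "ConvectionConfig",
    "air_properties",
    "grashof",
    "prandtl",
    "nusselt",
    "convective_coefficient",
    "natural_convection_coefficient",
]

G_STANDARD = 9.81  # m/s^2


class ConvectionError(ValueError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Thermophysical properties of the ambient fluid (air unless overridden).

    beta: 1/K volume-expansion coefficient; rho: kg/m^3; mu: Pa·s dynamic
    viscosity; cp: J/(kg K); k_cond: W/(m K).
    """

    beta: float
    rho: float
    mu: float
    cp: float
    k_cond: float

    def __post_init__(self):
        for name in ("beta", "rho", "mu", "cp", "k_cond"):
            if getattr(self, name) <= 0:
                raise ConvectionError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ConvectionConfig:
    """Correlation constants and geometry for Nu = c (Gr Pr)^m.

    Defaults c=0.59, m=0.25 are the vertical laminar plate/cylinder values.
    L is the characteristic (vertical) length in metres.
    """

    L: float
    c: float = 0.59
    m: float = 0.25
    g: float = G_STANDARD

    def __post_init__(self):
        if self.c <= 0:
            raise ConvectionError("c must be > 0")
        if not 0 < self.m < 1:
            raise ConvectionError("m must lie in (0, 1)")
        if self.L <= 0:
            raise ConvectionError("characteristic length L must be > 0")


# Dry air at 1 atm (T in K): rho kg/m^3, mu Pa·s, cp J/(kg K), k W/(m K).
_AIR_T = np.array([250.0, 300.0, 350.0])
_AIR_RHO = np.array([1.3947, 1.1614, 0.9950])
_AIR_MU = np.array([1.599e-5, 1.846e-5, 2.082e-5])
_AIR_CP = np.array([1006.0, 1007.0, 1009.0])
_AIR_K = np.array([0.02227, 0.0263, 0.0300])


def air_properties(T_kelvin: float) -> FluidProperties:
    """Dry-air properties at 1 atm, linearly interpolated over 250–350 K.

    beta = 1/T (ideal gas).  Temperatures outside the table range raise.
    """
    if not _AIR_T[0] <= T_kelvin <= _AIR_T[-1]:
        raise ConvectionError(
            f"film temperature {T_kelvin} K outside the air table range "
            f"{_AIR_T[0]}-{_AIR_T[-1]} K"
        )
    return FluidProperties(
        beta=1.0 / T_kelvin,
        rho=float(np.interp(T_kelvin, _AIR_T, _AIR_RHO)),
        mu=float(np.interp(T_kelvin, _AIR_T, _AIR_MU)),
        cp=float(np.interp(T_kelvin, _AIR_T, _AIR_CP)),
        k_cond=float(np.interp(T_kelvin, _AIR_T, _AIR_K)),
    )


def grashof(props: FluidProperties, delta_T: float, L: float,
            g: float = G_STANDARD) -> float:
    """Grashof number Gr = beta g dT rho^2 L^3 / mu^2 (buoyancy/viscous)."""
    if L <= 0:
        raise ConvectionError("characteristic length L must be > 0")
    if delta_T < 0:
        raise ConvectionError("delta_T must be >= 0")
    return props.beta * g * delta_T * props.rho**2 * L**3 / props.mu**2


def prandtl(props: FluidProperties) -> float:
    """Prandtl number Pr = cp mu / k (momentum/thermal diffusivity)."""
    return props.cp * props.mu / props.k_cond


def nusselt(Gr: float, Pr: float, config: ConvectionConfig) -> float:
    """Nusselt number Nu = c (Gr Pr)^m."""
    if Gr < 0:
        raise ConvectionError("Grashof number must be >= 0")
    if Pr <= 0:
        raise ConvectionError("Prandtl number must be > 0")
    return config.c * (Gr * Pr) ** config.m


def convective_coefficient(Nu: float, k_cond: float, L: float) -> float:
    """Film coefficient h_c = Nu k / L in W/(m^2 K)."""
    if L <= 0:
        raise ConvectionError("characteristic length L must be > 0")
    return Nu * k_cond / L


def natural_convection_coefficient(surface_T_C: float, ambient_T_C: float,
                                   config: ConvectionConfig,
                                   props: FluidProperties | None = None) -> float:
    """Full correlation chain: surface/ambient temperatures (degC) -> h_c.

    Air properties default to the built-in table evaluated at the film
    temperature (arithmetic mean of surface and ambient).
    """
    delta_T = abs(surface_T_C - ambient_T_C)
    if props is None:
        film_K = 273.15 + 0.5 * (surface_T_C + ambient_T_C)
        props = air_properties(film_K)
    Gr = grashof(props, delta_T, config.L, config.g)
    Nu = nusselt(Gr, prandtl(props), config)
    return convective_coefficient(Nu, props.k_cond, config.L)
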