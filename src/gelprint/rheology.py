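"""Pseudoplastic (power-law) rheology of gelatin solutions and gel-point detection.

Gelatin solutions are shear thinning: the apparent viscosity follows
``eta_a = tau / gamma_dot = k * gamma_dot**(n - 1)`` with consistency
coefficient ``k`` (Pa·s^n) and rheological index ``n`` (dimensionless,
``n < 1`` for a pseudoplastic fluid).  Above the sol–gel transition the
consistency coefficient thins exponentially with temperature,
``k_eff = k * exp(-b * (T - T_ref))``.

Two standard gel-point detectors are provided:

* the *viscosity mutation* point — the temperature of steepest change of a
  viscosity–temperature ramp (the abrupt surge as the network forms), and
* the *modulus crossover* — the temperature at which the storage modulus G'
  equals the loss modulus G'' in an oscillatory temperature sweep,
  equivalently where the loss tangent tan δ = G''/G' crosses 1.

For a 9 wt% gelatin solution both sit near 31 °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RheologyError",
    "FitError",
    "GelPointNotFound",
    "AmbiguousGelPoint",
    "RheogramPoint",
    "RheologySweep",
    "PowerLawModel",
    "ThermalRamp",
    "OscillatorySweep",
    "GelPointEstimate",
    "PowerLawFit",
    "apparent_viscosity",
    "shear_stress",
    "fit_power_law",
    "gel_point_from_viscosity",
    "loss_tangent",
    "classify_viscoelastic",
    "gel_point_from_crossover",
]


class RheologyError(ValueError):
    """Invalid rheological input (nonpositive shear rate, modulus, ...)."""


class FitError(RheologyError):
    """Power-law or regression fit cannot be performed."""


class GelPointNotFound(RheologyError):
    """No gel transition detectable in the supplied sweep."""


class AmbiguousGelPoint(RheologyError):
    """More than one candidate gel transition found."""

    def __init__(self, temperatures):
        self.temperatures = list(temperatures)
        super().__init__(
            "multiple modulus crossovers found at temperatures "
            + ", ".join(f"{t:.3g} degC" for t in self.temperatures)
        )


@dataclass(frozen=True)
class RheogramPoint:
    """One steady-shear measurement: shear rate (1/s), apparent viscosity
    (Pa·s) and, optionally, the shear stress (Pa, must equal eta * gamma_dot)."""

    shear_rate: float
    viscosity: float
    stress: float | None = None

    def __post_init__(self):
        if self.shear_rate <= 0:
            raise RheologyError(f"shear_rate must be > 0, got {self.shear_rate}")
        if self.viscosity <= 0:
            raise RheologyError(f"viscosity must be > 0, got {self.viscosity}")
        if self.stress is not None:
            expected = self.viscosity * self.shear_rate
            if abs(self.stress - expected) > 1e-9 * abs(expected):
                raise RheologyError(
                    f"stress {self.stress} inconsistent with viscosity*shear_rate "
                    f"= {expected}"
                )


@dataclass(frozen=True)
class RheologySweep:
    """A steady-shear flow sweep at fixed temperature and gelatin concentration."""

    temperature: float  # degC
    concentration: float  # wt% gelatin
    points: tuple[RheogramPoint, ...]

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 3:
            raise RheologyError("a sweep needs at least 3 points")
        rates = self.shear_rates
        if not np.all(np.diff(rates) > 0):
            raise RheologyError("shear rates must be strictly increasing")

    @property
    def shear_rates(self) -> np.ndarray:
        return np.array([p.shear_rate for p in self.points])

    @property
    def viscosities(self) -> np.ndarray:
        return np.array([p.viscosity for p in self.points])


@dataclass(frozen=True)
class PowerLawModel:
    """Power-law constitutive model with optional exponential thermal thinning.

    Parameters
    ----------
    k : consistency coefficient, Pa·s^n, at the reference temperature.
    n : rheological index (dimensionless); n < 1 is shear thinning.
    T_ref : reference temperature, degC.
    b : thermal-thinning coefficient, 1/degC;
        ``k_eff(T) = k * exp(-b * (T - T_ref))``.
    """

    k: float
    n: float
    T_ref: float = 25.0
    b: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise RheologyError(f"consistency coefficient k must be > 0, got {self.k}")
        if self.n <= 0:
            raise RheologyError(f"rheological index n must be > 0, got {self.n}")
        if self.n > 1:
            warnings.warn(
                f"n = {self.n} > 1 (shear thickening); unexpected for gelatin",
                stacklevel=3,
            )

    def k_eff(self, temperature=None):
        """Effective consistency coefficient at ``temperature`` (degC)."""
        if temperature is None:
            return self.k
        return self.k * np.exp(-self.b * (np.asarray(temperature) - self.T_ref))


@dataclass(frozen=True)
class ThermalRamp:
    """Viscosity versus temperature, temperatures strictly ascending."""

    temperatures: np.ndarray
    viscosities: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.viscosities, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "viscosities", v)
        if t.shape != v.shape:
            raise RheologyError("temperatures and viscosities must have equal length")
        if t.size < 5:
            raise RheologyError("a thermal ramp needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise RheologyError("temperatures must be strictly ascending")


@dataclass(frozen=True)
class OscillatorySweep:
    """Storage modulus G' and loss modulus G'' versus temperature."""

    temperatures: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        gp = np.asarray(self.storage_modulus, dtype=float)
        gpp = np.asarray(self.loss_modulus, dtype=float)
        for name, arr in (("temperatures", t), ("storage_modulus", gp), ("loss_modulus", gpp)):
            object.__setattr__(self, name, arr)
        if not (t.shape == gp.shape == gpp.shape):
            raise RheologyError("oscillatory sweep arrays must have equal length")
        if np.any(gp <= 0) or np.any(gpp <= 0):
            raise RheologyError("moduli must be strictly positive")


@dataclass(frozen=True)
class GelPointEstimate:
    temperature: float  # degC
    method: str  # "viscosity_mutation" | "modulus_crossover"


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted :class:`PowerLawModel` plus log-log OLS residual diagnostics."""

    model: PowerLawModel
    r_squared: float
    residual_std: float  # std of ln-viscosity residuals
    residuals: np.ndarray = field(repr=False, default=None)


def apparent_viscosity(model: PowerLawModel, shear_rate, temperature=None):
    """Apparent viscosity eta_a = k_eff * gamma_dot**(n-1) in Pa·s.

    ``shear_rate`` may be a scalar or array (1/s, strictly positive);
    ``temperature`` (degC) activates the exponential thinning factor.
    """
    gd = np.asarray(shear_rate, dtype=float)
    if np.any(gd <= 0):
        raise RheologyError("shear_rate must be strictly positive")
    out = model.k_eff(temperature) * gd ** (model.n - 1.0)
    return out if out.ndim else float(out)


def shear_stress(model: PowerLawModel, shear_rate, temperature=None):
    """Shear stress tau = k_eff * gamma_dot**n in Pa."""
    gd = np.asarray(shear_rate, dtype=float)
    if np.any(gd <= 0):
        raise RheologyError("shear_rate must be strictly positive")
    out = model.k_eff(temperature) * gd ** model.n
    return out if out.ndim else float(out)


def fit_power_law(sweep: RheologySweep) -> PowerLawFit:
    """Fit (k, n) by ordinary least squares of ln(eta) on ln(gamma_dot).

    The power law is linear in log-log space: ln eta = ln k + (n-1) ln gamma_dot,
    so the fit is a reproducible closed form.  Returns the model with residual
    diagnostics (R^2 and residual standard deviation in ln space).
    """
    gd = sweep.shear_rates
    eta = sweep.viscosities
    if gd.size < 3:
        raise FitError("need at least 3 points to fit a power law")
    x = np.log(gd)
    y = np.log(eta)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    model = PowerLawModel(k=float(np.exp(intercept)), n=float(slope + 1.0),
                          T_ref=sweep.temperature)
    return PowerLawFit(model=model, r_squared=r2,
                       residual_std=float(np.std(resid)), residuals=resid)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    # edge handling: pad by replication so the output length matches
    pad = window // 2
    padded = np.concatenate([np.repeat(values[0], pad), values,
                             np.repeat(values[-1], window - 1 - pad)])
    return np.convolve(padded, kernel, mode="valid")


def gel_point_from_viscosity(ramp: ThermalRamp, window: int = 3,
                             distinctness: float = 3.0) -> GelPointEstimate:
    """Gel point as the viscosity *mutation* (abrupt-change) temperature.

    The viscosities are smoothed by a centred moving average (``window``
    points), differentiated by central differences, and the temperature of
    maximum |d eta/dT| is returned.  If the maximum derivative is not
    distinct — ratio of max to median |derivative| below ``distinctness`` —
    the ramp has no abrupt change and :class:`GelPointNotFound` is raised.
    """
    smooth = _moving_average(ramp.viscosities, window)
    deriv = np.abs(np.gradient(smooth, ramp.temperatures))
    med = float(np.median(deriv))
    peak = float(np.max(deriv))
    if med <= 0 or peak / med < distinctness:
        raise GelPointNotFound(
            "no mutation point: maximum |d(eta)/dT| is not distinct "
            f"(max/median = {peak / med if med > 0 else np.inf:.2f} < {distinctness})"
        )
    t_star = float(ramp.temperatures[int(np.argmax(deriv))])
    return GelPointEstimate(temperature=t_star, method="viscosity_mutation")


def loss_tangent(storage_modulus, loss_modulus):
    """Loss tangent tan δ = G''/G' (dimensionless).

    tan δ < 1 means predominantly elastic (solid-like, gelled); tan δ > 1
    means predominantly viscous (liquid-like, sol).
    """
    gp = np.asarray(storage_modulus, dtype=float)
    gpp = np.asarray(loss_modulus, dtype=float)
    if np.any(gp <= 0) or np.any(gpp <= 0):
        raise RheologyError("moduli must be strictly positive")
    out = gpp / gp
    return out if out.ndim else float(out)


def classify_viscoelastic(tan_delta: float) -> str:
    """Classify a loss tangent: 'elastic' (<1), 'liquid' (>1), 'crossover' (=1)."""
    if tan_delta < 1.0:
        return "elastic"
    if tan_delta > 1.0:
        return "liquid"
    return "crossover"


def gel_point_from_crossover(osc: OscillatorySweep) -> GelPointEstimate:
    """Gel point as the G' = G'' crossover temperature.

    Locates the single sign change of G' - G'' along the sweep and linearly
    interpolates the crossing temperature.  Raises :class:`GelPointNotFound`
    if the moduli never cross and :class:`AmbiguousGelPoint` (listing all
    candidates) if they cross more than once.
    """
    t = osc.temperatures
    delta = osc.storage_modulus - osc.loss_modulus
    crossings = []
    for i in range(len(t) - 1):
        a, b = delta[i], delta[i + 1]
        if a == 0.0 and (i == 0 or delta[i - 1] != 0.0):
            crossings.append(float(t[i]))
        elif a * b < 0:
            frac = a / (a - b)
            crossings.append(float(t[i] + frac * (t[i + 1] - t[i])))
    if delta[-1] == 0.0:
        crossings.append(float(t[-1]))
    if not crossings:
        raise GelPointNotFound("no crossover: G' - G'' does not change sign")
    if len(crossings) > 1:
        raise AmbiguousGelPoint(crossings)
    return GelPointEstimate(temperature=crossings[0], method="modulus_crossover")
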