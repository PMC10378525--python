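"""Synthetic rheometer and calibration data with the structure the models assume.

These generators emulate the data products of a rheometer session on
gelatin solutions (3–12 wt%, 25–35 degC) and of a line-width calibration
print, so every analysis stage can be exercised without instrument data:

* flow sweeps: shear-thinning power-law rheograms over 0.1–100 1/s whose
  consistency coefficient rises with concentration (power law) and falls
  with temperature (exponential), with multiplicative lognormal noise;
* a viscosity–temperature ramp with a sigmoidal surge below the gel point
  (default 31 degC) on top of an exponentially thinning baseline;
* an oscillatory temperature sweep whose G'/G'' curves cross exactly once
  at the gel point (tan delta < 1 below it, > 1 above it);
* noisy line-width measurements around a known affine width law, plus the
  built-in reference calibration dataset of the four printed conditions.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .deposition import LinearLaw, WidthMeasurement
from .flow import ChannelGeometry
from .rheology import (
    OscillatorySweep,
    PowerLawModel,
    RheogramPoint,
    RheologySweep,
    ThermalRamp,
)

__all__ = [
    "SynthRheologyConfig",
    "SynthGelConfig",
    "ReferenceInputs",
    "synth_rheogram",
    "synth_thermal_ramp",
    "synth_oscillatory",
    "synth_line_widths",
    "reference_inputs",
]


@dataclass(frozen=True)
class SynthRheologyConfig:
    """Generator settings for flow sweeps.

    k(conc, T) = k_base * (conc / 9)**k_concentration_exponent
                        * exp(-b (T - T_ref));
    the defaults give a 9 wt% solution k = 5 Pa·s^n at 25 degC with n = 0.45,
    qualitatively matching the measured concentration/temperature orderings.
    """

    concentrations: tuple = (3.0, 6.0, 9.0, 12.0)
    temperatures: tuple = (25.0, 30.0, 35.0)
    k_base: float = 5.0
    k_concentration_exponent: float = 2.2
    n: float = 0.45
    b: float = 0.12
    T_ref: float = 25.0
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def consistency(self, concentration: float, temperature: float) -> float:
        return (self.k_base
                * (concentration / 9.0) ** self.k_concentration_exponent
                * np.exp(-self.b * (temperature - self.T_ref)))


@dataclass(frozen=True)
class SynthGelConfig:
    """Generator settings for the sol–gel transition data products."""

    gel_temperature: float = 31.0
    surge_magnitude: float = 30.0
    transition_width: float = 0.8
    baseline_viscosity: float = 1.0
    baseline_thinning: float = 0.02  # 1/degC, gentle thinning away from the surge
    seed: int = 0

    def __post_init__(self):
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


def synth_rheogram(config: SynthRheologyConfig, concentration: float,
                   temperature: float, n_points: int = 30) -> RheologySweep:
    """One shear-thinning flow sweep: log-spaced shear rates 0.1–100 1/s,
    eta = k(conc, T) gamma_dot**(n-1) with lognormal multiplicative noise."""
    rates = np.logspace(-1, 2, n_points)
    k = config.consistency(concentration, temperature)
    eta = k * rates ** (config.n - 1.0)
    if config.noise_cv > 0:
        rng = _rng(config.seed, round(concentration * 10), round(temperature * 10))
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        eta = eta * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_points)
    points = tuple(RheogramPoint(shear_rate=float(g), viscosity=float(e))
                   for g, e in zip(rates, eta))
    return RheologySweep(temperature=temperature, concentration=concentration,
                         points=points)


def synth_thermal_ramp(config: SynthGelConfig, t_min: float = 0.0,
                       t_max: float = 45.0, n_points: int = 451,
                       noise_cv: float = 0.0) -> ThermalRamp:
    """Viscosity–temperature ramp with a sigmoidal surge at the gel point.

    eta(T) = baseline(T) * (1 + surge * logistic((T_gel - T)/width)) with an
    exponentially thinning baseline, densely sampled so the mutation-point
    detector resolves the transition.
    """
    T = np.linspace(t_min, t_max, n_points)
    baseline = config.baseline_viscosity * np.exp(
        -config.baseline_thinning * (T - config.gel_temperature))
    surge = 1.0 + config.surge_magnitude * expit(
        (config.gel_temperature - T) / config.transition_width)
    eta = baseline * surge
    if noise_cv > 0:
        rng = _rng(config.seed, 1)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        eta = eta * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=T.size)
    return ThermalRamp(temperatures=T, viscosities=eta)


def synth_oscillatory(config: SynthGelConfig, t_min: float = 20.0,
                      t_max: float = 40.0, n_points: int = 201,
                      modulus_scale: float = 200.0,
                      tan_delta_width: float = 3.0) -> OscillatorySweep:
    """Oscillatory sweep crossing G' = G'' exactly at the gel temperature.

    tan delta = exp((T - T_gel)/tan_delta_width) is monotone in T, below 1
    (elastic) under the gel point and above 1 (liquid) over it; G'' decays
    gently with temperature and G' = G'' / tan delta.
    """
    T = np.linspace(t_min, t_max, n_points)
    tan_delta = np.exp((T - config.gel_temperature) / tan_delta_width)
    g_loss = modulus_scale * np.exp(-0.02 * (T - config.gel_temperature))
    g_storage = g_loss / tan_delta
    return OscillatorySweep(temperatures=T, storage_modulus=g_storage,
                            loss_modulus=g_loss)


def synth_line_widths(true_law: LinearLaw, inlet_velocities, noise_sd: float,
                      seed: int) -> list[WidthMeasurement]:
    """Width measurements = true_law(v_j) + Gaussian noise (sd in mm)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    v = np.asarray(inlet_velocities, dtype=float)
    widths = true_law(v)
    if noise_sd > 0:
        widths = widths + _rng(seed, 2).normal(0.0, noise_sd, size=v.size)
    return [WidthMeasurement(inlet_velocity=float(vj), measured_width=float(w))
            for vj, w in zip(v, widths)]


@dataclass(frozen=True)
class ReferenceInputs:
    """Built-in calibration dataset of the reference LDM printer.

    The four width measurements were taken at a 5 mm/s print speed with the
    default barrel/nozzle geometry.  ``layer_thickness`` is 0.5 mm — the
    value consistent with the published theoretical widths and regression
    laws; the nominal printer setting of 0.3 mm is retained as
    ``nominal_layer_thickness`` for completeness (the published laws are not
    mutually consistent with it).
    """

    geometry: ChannelGeometry
    measurements: tuple
    print_speed: float  # mm/s
    layer_thickness: float  # mm, reproduces the published laws
    nominal_layer_thickness: float  # mm, as reported in the printer settings
    actual_law_published: LinearLaw
    theoretical_law_published: LinearLaw
    error_law_published: LinearLaw
    rheology: PowerLawModel
    inlet_velocity_window: tuple  # mm/s process window
    print_speed_window: tuple  # mm/s process window


def reference_inputs() -> ReferenceInputs:
    """The printed constants of the reference calibration as a single bundle."""
    measurements = (
        WidthMeasurement(0.0156, 1.660),
        WidthMeasurement(0.0313, 2.280),
        WidthMeasurement(0.0469, 2.830),
        WidthMeasurement(0.0625, 3.320),
    )
    return ReferenceInputs(
        geometry=ChannelGeometry(),
        measurements=measurements,
        print_speed=5.0,
        layer_thickness=0.5,
        nominal_layer_thickness=0.3,
        actual_law_published=LinearLaw(intercept=1.1415, slope=35.3344),
        theoretical_law_published=LinearLaw(intercept=0.1075, slope=61.529),
        error_law_published=LinearLaw(intercept=1.0345, slope=-26.195),
        rheology=PowerLawModel(k=5.0, n=0.45, T_ref=25.0, b=0.12),
        inlet_velocity_window=(0.03, 0.09),
        print_speed_window=(2.0, 8.0),
    )
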