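"""Extrusion-speed / print-speed matching via deposited line-width calibration.

A line deposited by the travelling nozzle has a stadium cross-section
(rectangle of height h capped by two half-discs of diameter h).  Volume
conservation between the piston (barrel bore d1, inlet velocity v_j) and
the deposited line (print speed v_c, width d2, layer thickness h) gives

    v_j * pi d1^2 / 4 = v_c * [(d2 - h) h + pi h^2 / 4]
    d2 = v_j pi d1^2 / (4 v_c h) + (4 - pi) h / 4
    v_c = k v_j,  k = pi d1^2 / (4 d2 h - 4 h^2 + pi h^2)

Measured widths deviate from this ideal by an affine error law
D(v_j) = d3 - d2 fitted from calibration prints; folding D back into the
volume balance yields the corrected matching factor

    k1 = pi d1^2 / (4 h d2 + (pi - 4) h^2 - 4 a_D h + 4 b_D h v_j)

with (a_D, b_D) = (intercept, -slope) of D, and the optimal inlet velocity
for a target width solves v_c = k1(v_j) v_j in closed form.  A ``reference``
mode hard-codes the constants 4.14 and 104.78 of the calibration performed
on the reference printer (h = 0.5 mm, d1 = 14 mm, v_c = 5 mm/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepositionError",
    "DepositionParams",
    "LinearLaw",
    "WidthMeasurement",
    "WidthCalibration",
    "stadium_area",
    "theoretical_width",
    "theoretical_width_law",
    "speed_ratio_k",
    "fit_width_law",
    "calibrate",
    "corrected_k1",
    "optimal_inlet_velocity",
    "REFERENCE_4AD",
    "REFERENCE_4BD",
]

# Printed correction constants of the reference calibration: 4*a_D and 4*b_D
# as published (4 x 1.0345 = 4.138 rounded to 4.14; 4 x 26.195 = 104.78).
REFERENCE_4AD = 4.14
REFERENCE_4BD = 104.78


class DepositionError(ValueError):
    pass


@dataclass(frozen=True)
class DepositionParams:
    """Process parameters of one deposition condition (mm, mm/s)."""

    inlet_velocity: float
    deposition_speed: float
    layer_thickness: float
    barrel_inner_diameter: float = 14.0
    nozzle_diameter: float = 1.0

    def __post_init__(self):
        for name in ("inlet_velocity", "deposition_speed", "layer_thickness",
                     "barrel_inner_diameter", "nozzle_diameter"):
            if getattr(self, name) <= 0:
                raise DepositionError(f"{name} must be > 0")


@dataclass(frozen=True)
class LinearLaw:
    """Affine law width(v_j) = intercept + slope * v_j (mm, mm per mm/s)."""

    intercept: float
    slope: float

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise DepositionError("law coefficients must be finite")

    def __call__(self, inlet_velocity):
        return self.intercept + self.slope * np.asarray(inlet_velocity, dtype=float)

    def __sub__(self, other: "LinearLaw") -> "LinearLaw":
        return LinearLaw(self.intercept - other.intercept, self.slope - other.slope)


@dataclass(frozen=True)
class WidthMeasurement:
    """One measured deposition line width d3 (mm) at an inlet velocity (mm/s)."""

    inlet_velocity: float
    measured_width: float

    def __post_init__(self):
        if self.inlet_velocity <= 0 or self.measured_width <= 0:
            raise DepositionError("inlet velocity and width must be > 0")


@dataclass(frozen=True)
class WidthCalibration:
    """Fitted actual-width law, analytic theoretical law and their difference D."""

    actual_law: LinearLaw
    theoretical_law: LinearLaw
    error_law: LinearLaw
    mode: str = "fitted"  # "fitted" | "reference"


def stadium_area(width: float, h: float) -> float:
    """Cross-sectional area (mm^2) of a stadium: (w - h) h + pi h^2 / 4.

    width = h degenerates to a circle of diameter h; width < h is unphysical.
    """
    if h <= 0:
        raise DepositionError("layer thickness h must be > 0")
    if width < h:
        raise DepositionError(f"width {width} < layer thickness {h}")
    return (width - h) * h + np.pi * h**2 / 4.0


def theoretical_width(v_j: float, v_c: float, d1: float, h: float) -> float:
    """Volume-balance line width d2 = v_j pi d1^2 / (4 v_c h) + (4 - pi) h / 4."""
    if min(v_j, v_c, d1, h) <= 0:
        raise DepositionError("all inputs must be > 0")
    d2 = v_j * np.pi * d1**2 / (4.0 * v_c * h) + (4.0 - np.pi) * h / 4.0
    if d2 < h:
        warnings.warn(
            f"theoretical width {d2:.4g} mm is narrower than the layer "
            f"thickness {h} mm (unphysical stadium)", stacklevel=2)
    return float(d2)


def theoretical_width_law(v_c: float, d1: float, h: float) -> LinearLaw:
    """The volume balance is affine in v_j: slope pi d1^2/(4 v_c h),
    intercept (4 - pi) h / 4."""
    if min(v_c, d1, h) <= 0:
        raise DepositionError("all inputs must be > 0")
    return LinearLaw(intercept=(4.0 - np.pi) * h / 4.0,
                     slope=np.pi * d1**2 / (4.0 * v_c * h))


def speed_ratio_k(d1: float, d2: float, h: float) -> float:
    """Ideal matching factor k = pi d1^2 / (4 d2 h - 4 h^2 + pi h^2),
    satisfying v_c = k v_j at exact volume balance."""
    if min(d1, h) <= 0:
        raise DepositionError("d1 and h must be > 0")
    if d2 < h:
        raise DepositionError(f"d2 = {d2} must be >= h = {h}")
    denom = 4.0 * d2 * h - 4.0 * h**2 + np.pi * h**2
    if denom <= 0:
        raise DepositionError("nonpositive denominator in speed ratio")
    return float(np.pi * d1**2 / denom)


def fit_width_law(measurements) -> LinearLaw:
    """OLS of measured width on inlet velocity."""
    ms = list(measurements)
    if len(ms) < 2:
        raise DepositionError("need at least 2 measurements")
    v = np.array([m.inlet_velocity for m in ms])
    w = np.array([m.measured_width for m in ms])
    if np.ptp(v) == 0:
        raise DepositionError("all inlet velocities are equal; cannot fit a line")
    slope, intercept = np.polyfit(v, w, 1)
    return LinearLaw(intercept=float(intercept), slope=float(slope))


def calibrate(measurements, v_c: float, d1: float, h: float) -> WidthCalibration:
    """Fit the actual-width law and difference it against the analytic
    theoretical law to obtain the width-error law D(v_j) = d3 - d2."""
    actual = fit_width_law(measurements)
    theo = theoretical_width_law(v_c, d1, h)
    return WidthCalibration(actual_law=actual, theoretical_law=theo,
                            error_law=actual - theo, mode="fitted")


def _correction_constants(error_law: LinearLaw | None, mode: str):
    """(4*a_D, 4*b_D) of the correction denominator for the given mode."""
    if mode == "reference":
        return REFERENCE_4AD, REFERENCE_4BD
    if mode == "fitted":
        if error_law is None:
            raise DepositionError("fitted mode needs an error law")
        return 4.0 * error_law.intercept, -4.0 * error_law.slope
    raise DepositionError(f"unknown mode {mode!r}; use 'fitted' or 'reference'")


def corrected_k1(d1: float, h: float, target_width: float, v_j: float,
                 error_law: LinearLaw | None = None,
                 mode: str = "fitted") -> float:
    """Corrected matching factor
    k1 = pi d1^2 / (4 h d2 + (pi - 4) h^2 - 4 a_D h + 4 b_D h v_j).

    ``mode='reference'`` uses the printed calibration constants 4.14 and
    104.78 instead of 4 a_D / 4 b_D from ``error_law``.
    """
    if min(d1, h, target_width, v_j) <= 0:
        raise DepositionError("all inputs must be > 0")
    four_ad, four_bd = _correction_constants(error_law, mode)
    denom = (4.0 * h * target_width + (np.pi - 4.0) * h**2
             - four_ad * h + four_bd * h * v_j)
    if denom <= 0:
        raise DepositionError("nonpositive denominator in corrected k1")
    return float(np.pi * d1**2 / denom)


def optimal_inlet_velocity(target_width: float, v_c: float,
                           calibration: WidthCalibration | None = None,
                           d1: float = 14.0, h: float = 0.5,
                           mode: str | None = None) -> float:
    """Inlet velocity solving v_c = k1(v_j) v_j for a target line width.

    Clearing the denominator makes the matching relation linear in v_j:
    v_j = v_c A / (pi d1^2 - v_c B) with A the v_j-independent part of the
    correction denominator and B = 4 b_D h.  ``mode`` defaults to the
    calibration's mode ('reference' if no calibration is given).
    """
    if target_width <= h:
        raise DepositionError(f"target width must exceed layer thickness {h}")
    if v_c <= 0:
        raise DepositionError("print speed must be > 0")
    if mode is None:
        mode = calibration.mode if calibration is not None else "reference"
    error_law = calibration.error_law if calibration is not None else None
    four_ad, four_bd = _correction_constants(error_law, mode)
    A = (4.0 * h * target_width + (np.pi - 4.0) * h**2 - four_ad * h)
    B = four_bd * h
    denom = np.pi * d1**2 - v_c * B
    v_j = v_c * A / denom
    if denom <= 0 or v_j <= 0:
        raise DepositionError(
            "no positive inlet velocity solves the matching relation for "
            f"target width {target_width} mm at print speed {v_c} mm/s")
    return float(v_j)
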