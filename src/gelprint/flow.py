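"""Quasi-1D power-law hydraulics of the barrel–taper–nozzle extrusion channel.

The channel is a vertical cylinder (barrel, inner diameter 14 mm) that
contracts through a conical taper to a short cylindrical nozzle land
(outlet diameter 1 mm, 58 mm inlet-to-outlet).  The piston drives the melt
at a constant inlet velocity, so the volumetric flow rate Q is fixed and the
flow at every axial station is treated as fully developed laminar power-law
pipe flow (lubrication approximation):

    u(r)      = u_max * (1 - (r/R)**((n+1)/n)),  u_max = (3n+1)/(n+1) * Q/(pi R^2)
    gamma_w   = (3n+1)/(4n) * 4Q/(pi R^3)        (Rabinowitsch–Mooney)
    dp/dz     = 2 tau_w / R,  tau_w = k_eff(T) * gamma_w**n

Working units follow the printer: lengths mm, velocities mm/s, flow mm^3/s;
stresses and pressures stay in Pa (the mm cancel in the shear rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rheology import PowerLawModel

__all__ = [
    "FlowError",
    "ChannelGeometry",
    "VelocityProfile",
    "radius_profile",
    "volumetric_flow",
    "mean_outlet_velocity",
    "power_law_velocity_profile",
    "wall_shear_rate",
    "pressure_gradient",
    "pressure_profile",
    "pressure_drop",
    "segment_z_grid",
]

ATM = 101325.0  # Pa


class FlowError(ValueError):
    pass


@dataclass(frozen=True)
class ChannelGeometry:
    """Barrel–taper–nozzle channel dimensions in mm.

    Defaults follow the reference printer: 14 mm barrel bore, 58 mm
    inlet-to-outlet, 1 mm nozzle.  Taper and land lengths are design
    parameters (the cone and short straight outlet section).
    ``jacket_length`` is the heated-sleeve coverage measured from the inlet.
    """

    barrel_inner_diameter: float = 14.0
    barrel_outer_diameter: float = 17.0
    total_length: float = 58.0
    taper_length: float = 5.0
    nozzle_land_length: float = 3.0
    nozzle_diameter: float = 1.0
    jacket_length: float = 45.0

    def __post_init__(self):
        if not 0 < self.nozzle_diameter < self.barrel_inner_diameter:
            raise FlowError("need 0 < nozzle_diameter < barrel_inner_diameter")
        if self.taper_length + self.nozzle_land_length >= self.total_length:
            raise FlowError("taper + land must be shorter than the channel")
        if self.taper_length <= 0 or self.nozzle_land_length <= 0:
            raise FlowError("taper and land lengths must be positive")

    @property
    def barrel_length(self) -> float:
        return self.total_length - self.taper_length - self.nozzle_land_length

    @property
    def barrel_radius(self) -> float:
        return self.barrel_inner_diameter / 2.0

    @property
    def nozzle_radius(self) -> float:
        return self.nozzle_diameter / 2.0


def radius_profile(geometry: ChannelGeometry, z):
    """Channel inner radius R(z) in mm; z measured from the inlet (piston).

    Piecewise: constant barrel radius, linear cone over the taper, constant
    nozzle radius over the land.  ``z`` may be scalar or array.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0) or np.any(z_arr > geometry.total_length):
        raise FlowError(
            f"z must lie within [0, {geometry.total_length}] mm"
        )
    zb = geometry.barrel_length
    zt = zb + geometry.taper_length
    r = np.where(
        z_arr <= zb,
        geometry.barrel_radius,
        np.where(
            z_arr >= zt,
            geometry.nozzle_radius,
            geometry.barrel_radius
            + (z_arr - zb)
            / geometry.taper_length
            * (geometry.nozzle_radius - geometry.barrel_radius),
        ),
    )
    return r if r.ndim else float(r)


def volumetric_flow(inlet_velocity: float, barrel_inner_diameter: float) -> float:
    """Q = v_j * pi * d1^2 / 4 in mm^3/s (incompressible piston flow)."""
    if inlet_velocity < 0 or barrel_inner_diameter <= 0:
        raise FlowError("inlet velocity must be >= 0 and diameter > 0")
    return inlet_velocity * np.pi * barrel_inner_diameter**2 / 4.0


def mean_outlet_velocity(Q: float, nozzle_diameter: float) -> float:
    """Continuity-implied section-average speed Q / (pi d^2 / 4) in mm/s."""
    if Q < 0 or nozzle_diameter <= 0:
        raise FlowError("Q must be >= 0 and nozzle diameter > 0")
    return Q / (np.pi * nozzle_diameter**2 / 4.0)


@dataclass(frozen=True)
class VelocityProfile:
    """Fully developed power-law pipe-flow profile at one axial station."""

    r: np.ndarray  # mm, 0..R
    u: np.ndarray  # mm/s
    u_max: float  # centreline speed, mm/s
    u_mean: float  # section-average speed, mm/s


def power_law_velocity_profile(Q: float, R: float, n: float,
                               r=None, n_points: int = 101) -> VelocityProfile:
    """u(r) = u_max (1 - (r/R)^((n+1)/n)) with the flux normalised to Q.

    The centreline speed is u_max = (3n+1)/(n+1) * Q / (pi R^2); the profile
    integrates to Q exactly.  ``r`` defaults to a uniform grid of
    ``n_points`` radii spanning [0, R].
    """
    if n <= 0:
        raise FlowError("rheological index n must be > 0")
    if Q <= 0 or R <= 0:
        raise FlowError("Q and R must be > 0")
    if r is None:
        r = np.linspace(0.0, R, n_points)
    r = np.asarray(r, dtype=float)
    u_mean = Q / (np.pi * R**2)
    u_max = (3.0 * n + 1.0) / (n + 1.0) * u_mean
    u = u_max * (1.0 - (r / R) ** ((n + 1.0) / n))
    return VelocityProfile(r=r, u=u, u_max=float(u_max), u_mean=float(u_mean))


def wall_shear_rate(Q: float, R: float, n: float) -> float:
    """Rabinowitsch–Mooney wall shear rate (3n+1)/(4n) * 4Q/(pi R^3), 1/s."""
    if n <= 0 or Q < 0 or R <= 0:
        raise FlowError("need n > 0, Q >= 0, R > 0")
    return (3.0 * n + 1.0) / (4.0 * n) * 4.0 * Q / (np.pi * R**3)


def pressure_gradient(Q: float, R: float, model: PowerLawModel,
                      T: float | None = None) -> float:
    """Magnitude of dp/dz in Pa/mm for power-law pipe flow.

    tau_w = k_eff(T) * gamma_w**n, dp/dz = 2 tau_w / R; pressure falls
    toward the outlet.  Q = 0 gives 0.
    """
    if Q == 0:
        return 0.0
    gw = wall_shear_rate(Q, R, model.n)
    tau_w = float(model.k_eff(T)) * gw**model.n
    return 2.0 * tau_w / R


def segment_z_grid(geometry: ChannelGeometry, nz: int) -> np.ndarray:
    """Axial grid (mm) with nodes on both taper breakpoints.

    Nodes are allocated to barrel/taper/land proportionally to length with a
    minimum of 5 per segment, so the piecewise-smooth radius profile is
    resolved on every segment.
    """
    if nz < 10:
        raise FlowError("grid too coarse: need at least 10 axial stations")
    lengths = [geometry.barrel_length, geometry.taper_length,
               geometry.nozzle_land_length]
    total = geometry.total_length
    counts = [max(5, int(round(nz * L / total))) for L in lengths]
    z0 = 0.0
    pieces = []
    for L, cnt in zip(lengths, counts):
        seg = np.linspace(z0, z0 + L, cnt + 1)
        pieces.append(seg if not pieces else seg[1:])
        z0 += L
    return np.concatenate(pieces)


def _segment_integral(R0: float, R1: float, dz: float, n: float) -> float:
    """Integral of R(z)**-(3n+1) over an interval where R varies linearly."""
    if R0 == R1:
        return dz * R0 ** -(3.0 * n + 1.0)
    m = (R1 - R0) / dz
    return (R1 ** (-3.0 * n) - R0 ** (-3.0 * n)) / (-3.0 * n * m)


def pressure_profile(geometry: ChannelGeometry, Q: float, model: PowerLawModel,
                     z: np.ndarray | None = None, T_of_z=None,
                     outlet_pressure: float = ATM) -> tuple[np.ndarray, np.ndarray]:
    """Axial pressure p(z) in Pa with p(outlet) = outlet_pressure.

    dp/dz = A(T) R(z)**-(3n+1) with A = 2 k_eff ((3n+1)/(4n) * 4Q/pi)**n is
    integrated exactly per grid interval (R is linear within each segment),
    with k_eff evaluated at the interval-mean temperature.  ``T_of_z`` is a
    callable or per-node array of section-mean temperatures (degC); None
    means isothermal at the model's reference temperature.

    Returns (z, p).  Fewer than 10 axial stations raises :class:`FlowError`.
    """
    if z is None:
        z = segment_z_grid(geometry, 60)
    z = np.asarray(z, dtype=float)
    if z.size < 10:
        raise FlowError("grid too coarse: need at least 10 axial stations")
    R = np.asarray(radius_profile(geometry, z))
    if T_of_z is None:
        T_nodes = np.full(z.size, model.T_ref)
    elif callable(T_of_z):
        T_nodes = np.asarray(T_of_z(z), dtype=float)
    else:
        T_nodes = np.asarray(T_of_z, dtype=float)
        if T_nodes.shape != z.shape:
            raise FlowError("T_of_z array must match the z grid")
    n = model.n
    coef = (3.0 * n + 1.0) / (4.0 * n) * 4.0 / np.pi
    drops = np.zeros(z.size - 1)
    if Q > 0:
        for i in range(z.size - 1):
            dz = z[i + 1] - z[i]
            T_mid = 0.5 * (T_nodes[i] + T_nodes[i + 1])
            A = 2.0 * float(model.k_eff(T_mid)) * (coef * Q) ** n
            drops[i] = A * _segment_integral(R[i], R[i + 1], dz, n)
    p = np.empty(z.size)
    p[-1] = outlet_pressure
    p[:-1] = outlet_pressure + np.cumsum(drops[::-1])[::-1]
    return z, p


def pressure_drop(geometry: ChannelGeometry, Q: float, model: PowerLawModel,
                  z: np.ndarray | None = None, T_of_z=None,
                  outlet_pressure: float = ATM) -> float:
    """Inlet-to-outlet pressure difference p(0) - p(L) in Pa."""
    _, p = pressure_profile(geometry, Q, model, z=z, T_of_z=T_of_z,
                            outlet_pressure=outlet_pressure)
    return float(p[0] - p[-1])
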