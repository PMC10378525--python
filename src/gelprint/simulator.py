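"""Non-isothermal quasi-1D extrusion-channel simulator with bang-bang heating.

The commercial 3D FEM of the extrusion head is replaced by a desk-scale
model that keeps every physical trend of interest:

* **Flow** — lubrication theory: at every axial station the velocity is the
  fully developed power-law pipe-flow profile for the (fixed, incompressible)
  flow rate Q and the local radius R(z).  Because the profile shape depends
  only on the rheological index n, the velocity and shear-rate fields are
  independent of temperature and of the consistency coefficient; only the
  pressure feels k_eff(T).
* **Heat** — axisymmetric advection–diffusion on a radius-normalised grid
  (s = r/R(z), axial station z):
  ``rho cp (dT/dt + u dT/dz) = k (1/r d/dr(r dT/dr) + d2T/dz2)``.
  Radial diffusion is integrated implicitly (pre-factorised tridiagonal
  solves, one per station), axial advection by explicit first-order upwind
  and axial diffusion explicitly; the time step is checked against the
  advective CFL bound.
* **Boundaries** — the jacketed part of the barrel wall is a Dirichlet
  boundary at a wall temperature that relaxes first-order toward the heating
  jacket set point while the heater is on (and toward ambient when off); a
  bang-bang thermostat with a 30–32 degC hysteresis band switches the heater
  using the wall thermocouple.  The unjacketed exterior (barrel bottom,
  taper, nozzle) loses heat to the chilled ambient through a Robin boundary
  with the natural-convection film coefficient.  The inlet is held at the
  feed temperature; the outlet is an advective outflow.

Viscous dissipation, inertia and gravity are neglected (mm/s speeds, high
viscosity), and conduction in the metal parts is lumped into the boundary
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import simpson

from . import convection as conv
from .flow import (
    ATM,
    ChannelGeometry,
    FlowError,
    pressure_profile,
    radius_profile,
    segment_z_grid,
    volumetric_flow,
)
from .rheology import PowerLawModel

__all__ = [
    "SimulationError",
    "StabilityError",
    "ProcessConditions",
    "MaterialProperties",
    "ThermostatState",
    "GridSpec",
    "FieldState",
    "SimulationResult",
    "thermostat_step",
    "initial_state",
    "compute_flow_fields",
    "viscosity_field",
    "admissible_dt",
    "step_thermal",
    "run_simulation",
]


class SimulationError(RuntimeError):
    pass


class StabilityError(SimulationError):
    """Time step violates the explicit advection stability bound."""


@dataclass(frozen=True)
class ProcessConditions:
    """Boundary and initial conditions of one extrusion run.

    Velocities in mm/s, temperatures in degC, pressure in Pa.  The default
    initial wall/block temperatures are the measured cold-start values of
    the reference printer at 5 degC ambient.
    """

    inlet_velocity: float = 0.03
    initial_material_temperature: float = 30.0
    jacket_setpoint: float = 45.0
    ambient_temperature: float = 5.0
    outlet_pressure: float = ATM
    initial_barrel_wall_temperature: float = 24.3
    initial_block_temperature: float = 13.5

    def __post_init__(self):
        if self.inlet_velocity <= 0:
            raise SimulationError("inlet_velocity must be > 0")
        for name in ("initial_material_temperature", "jacket_setpoint",
                     "ambient_temperature", "initial_barrel_wall_temperature",
                     "initial_block_temperature"):
            t = getattr(self, name)
            if not -20.0 <= t <= 100.0:
                raise SimulationError(f"{name} = {t} degC outside -20..100 degC")


@dataclass(frozen=True)
class MaterialProperties:
    """Rheology plus thermal properties of the gelatin solution.

    Dilute aqueous gels are thermally water-like; the defaults are
    density 1000 kg/m^3, cp 4000 J/(kg K), k 0.55 W/(m K), all overridable.
    ``k_cond = 0`` switches conduction off (useful for pure-advection tests).
    """

    rheology: PowerLawModel
    density: float = 1000.0
    cp: float = 4000.0
    k_cond: float = 0.55

    def __post_init__(self):
        if self.density <= 0 or self.cp <= 0 or self.k_cond < 0:
            raise SimulationError("density and cp must be > 0, k_cond >= 0")

    @property
    def thermal_diffusivity(self) -> float:
        """alpha = k / (rho cp) in m^2/s."""
        return self.k_cond / (self.density * self.cp)


@dataclass(frozen=True)
class ThermostatState:
    """Bang-bang heater state with a hysteresis band (degC)."""

    heater_on: bool = False
    lower_band: float = 30.0
    upper_band: float = 32.0

    def __post_init__(self):
        if not self.lower_band < self.upper_band:
            raise SimulationError("need lower_band < upper_band")


def thermostat_step(state: ThermostatState, thermocouple_T: float) -> ThermostatState:
    """One thermostat decision: stop above the band, start below it,
    otherwise keep the current heater state (hysteresis)."""
    if thermocouple_T > state.upper_band:
        return replace(state, heater_on=False)
    if thermocouple_T < state.lower_band:
        return replace(state, heater_on=True)
    return state


@dataclass(frozen=True)
class GridSpec:
    """Discretisation: nr radial nodes (s = r/R in [0,1]), nz axial stations
    split over barrel/taper/land, advective CFL number, optional fixed dt (s)
    and the output recording interval (s)."""

    nr: int = 33
    nz: int = 80
    cfl: float = 0.8
    dt: float | None = None
    record_interval: float = 1.0

    def __post_init__(self):
        if self.nr < 5 or self.nz < 10:
            raise SimulationError("grid too coarse: need nr >= 5 and nz >= 10")
        if not 0 < self.cfl <= 1:
            raise SimulationError("cfl must lie in (0, 1]")


@dataclass
class FieldState:
    """Axisymmetric fields on the (s, z) grid at one instant.

    All 2-D arrays are shaped (nr, nz); z and R in mm, T in degC,
    u in mm/s, shear_rate in 1/s, viscosity in Pa·s, pressure in Pa.
    """

    time: float
    z: np.ndarray
    R: np.ndarray
    s: np.ndarray
    T: np.ndarray
    u: np.ndarray
    shear_rate: np.ndarray
    viscosity: np.ndarray
    pressure: np.ndarray

    def section_mean_T(self) -> np.ndarray:
        """Area-weighted section-mean temperature per axial station."""
        return 2.0 * simpson(self.T * self.s[:, None], x=self.s, axis=0)

    def outlet_mean_temperature(self) -> float:
        return float(self.section_mean_T()[-1])

    def section_flow_rates(self) -> np.ndarray:
        """Volumetric flow rate (mm^3/s) per station from the velocity field."""
        integrand = self.u * self.s[:, None]
        return 2.0 * np.pi * self.R**2 * simpson(integrand, x=self.s, axis=0)

    def centerline_temperature(self) -> np.ndarray:
        return self.T[0, :].copy()


def viscosity_field(fields: FieldState, material: MaterialProperties,
                    gamma_min: float = 1e-3) -> np.ndarray:
    """Pointwise apparent viscosity eta = k_eff(T) * gamma_dot**(n-1).

    The shear rate is floored at ``gamma_min`` (1/s) before the power is
    taken: for n < 1 the power law diverges at the centreline where the
    shear rate vanishes.
    """
    model = material.rheology
    gd = np.maximum(fields.shear_rate, gamma_min)
    return model.k_eff(fields.T) * gd ** (model.n - 1.0)


def compute_flow_fields(geometry: ChannelGeometry, conditions: ProcessConditions,
                        material: MaterialProperties, T: np.ndarray,
                        s: np.ndarray, z: np.ndarray, time: float = 0.0,
                        gamma_min: float = 1e-3) -> FieldState:
    """Quasi-steady flow solution consistent with the temperature field T.

    Velocity and shear-rate fields follow from Q, R(z) and n alone; the
    pressure profile integrates the power-law gradient with k_eff evaluated
    at the section-mean temperature.
    """
    model = material.rheology
    n = model.n
    Q = volumetric_flow(conditions.inlet_velocity, geometry.barrel_inner_diameter)
    R = np.asarray(radius_profile(geometry, z))
    u_mean = Q / (np.pi * R**2)
    u_max = (3.0 * n + 1.0) / (n + 1.0) * u_mean
    profile_shape = 1.0 - s[:, None] ** ((n + 1.0) / n)
    u = u_max[None, :] * profile_shape
    gamma_w = (3.0 * n + 1.0) / (4.0 * n) * 4.0 * Q / (np.pi * R**3)
    shear = gamma_w[None, :] * s[:, None] ** (1.0 / n)
    state = FieldState(time=time, z=z, R=R, s=s, T=T, u=u, shear_rate=shear,
                       viscosity=np.empty_like(u), pressure=np.empty_like(z))
    state.viscosity = viscosity_field(state, material, gamma_min)
    T_mean = state.section_mean_T()
    _, p = pressure_profile(geometry, Q, model, z=z, T_of_z=T_mean,
                            outlet_pressure=conditions.outlet_pressure)
    state.pressure = p
    return state


def initial_state(geometry: ChannelGeometry, conditions: ProcessConditions,
                  material: MaterialProperties, grid: GridSpec) -> FieldState:
    """Fields at t = 0: material uniformly at the feed temperature."""
    z = segment_z_grid(geometry, grid.nz)
    s = np.linspace(0.0, 1.0, grid.nr)
    T = np.full((grid.nr, z.size), conditions.initial_material_temperature,
                dtype=float)
    return compute_flow_fields(geometry, conditions, material, T, s, z)


def _exterior_film_coefficient(geometry: ChannelGeometry,
                               conditions: ProcessConditions,
                               convection_config: conv.ConvectionConfig | None) -> float:
    """Natural-convection h (W/m^2 K) for the unjacketed exterior surfaces.

    The film temperature uses the measured cold-start wall temperature as
    the surface estimate; the characteristic length defaults to the exposed
    (unjacketed) length of the channel.
    """
    if convection_config is None:
        exposed_mm = max(geometry.total_length - geometry.jacket_length, 1.0)
        convection_config = conv.ConvectionConfig(L=exposed_mm * 1e-3)
    return conv.natural_convection_coefficient(
        conditions.initial_barrel_wall_temperature,
        conditions.ambient_temperature, convection_config)


class _ThermalStepper:
    """Pre-factorised operator for one thermal time step on a fixed grid."""

    def __init__(self, geometry: ChannelGeometry, conditions: ProcessConditions,
                 material: MaterialProperties, s: np.ndarray, z: np.ndarray,
                 u: np.ndarray, dt: float, h_exterior: float):
        self.conditions = conditions
        self.material = material
        self.dt = dt
        self.s = s
        self.z = z
        nr, nz = u.shape
        self.nr, self.nz = nr, nz
        R_m = np.asarray(radius_profile(geometry, z)) * 1e-3
        self.u_m = u * 1e-3  # m/s
        self.dz_m = np.diff(z) * 1e-3
        # node "cell widths" (face-to-face) for the limited advection scheme
        self.dzc_m = np.empty(z.size)
        self.dzc_m[1:-1] = 0.5 * (self.dz_m[:-1] + self.dz_m[1:])
        self.dzc_m[0] = self.dz_m[0]
        self.dzc_m[-1] = self.dz_m[-1]
        alpha = material.thermal_diffusivity
        self.alpha = alpha
        self.jacketed = z <= min(geometry.jacket_length, geometry.barrel_length)
        self.h_ext = h_exterior

        ds = s[1] - s[0]
        a = np.zeros((nr, nz))
        b = np.ones((nr, nz))
        c = np.zeros((nr, nz))
        if alpha > 0.0:
            beta = alpha * dt / (R_m**2 * ds**2)  # per station
            # axis node: limit of the cylindrical Laplacian
            b[0, :] = 1.0 + 4.0 * beta
            c[0, :] = -4.0 * beta
            # interior annuli
            for i in range(1, nr - 1):
                w_minus = (s[i] - 0.5 * ds) / s[i]
                w_plus = (s[i] + 0.5 * ds) / s[i]
                a[i, :] = -beta * w_minus
                c[i, :] = -beta * w_plus
                b[i, :] = 1.0 + beta * (w_minus + w_plus)
            # wall node: Dirichlet under the jacket; elsewhere a conservative
            # half-cell finite-volume balance with the Robin exterior flux
            robin = ~self.jacketed
            s_face = 1.0 - 0.5 * ds
            s_bar = 1.0 - 0.25 * ds
            G1 = alpha * dt * s_face * 2.0 / (R_m**2 * ds**2 * s_bar)
            G2 = (alpha * dt * h_exterior * 2.0
                  / (material.k_cond * R_m * ds * s_bar))
            a[nr - 1, self.jacketed] = 0.0
            b[nr - 1, self.jacketed] = 1.0
            a[nr - 1, robin] = -G1[robin]
            b[nr - 1, robin] = 1.0 + G1[robin] + G2[robin]
            self._wall_G2 = G2
            # pre-factorise (Thomas forward elimination is RHS-independent)
            cp = np.zeros_like(c)
            inv_den = np.zeros_like(b)
            inv_den[0] = 1.0 / b[0]
            cp[0] = c[0] * inv_den[0]
            for i in range(1, nr):
                inv_den[i] = 1.0 / (b[i] - a[i] * cp[i - 1])
                cp[i] = c[i] * inv_den[i]
            self._a, self._cp, self._inv_den = a, cp, inv_den
            self._b, self._c = b, c  # kept for external verification

    def admissible_dt(self, cfl: float = 1.0) -> float:
        """Largest stable dt (s) for the explicit advection/axial diffusion.

        The limited second-order upwind advection is monotone for an
        advective Courant number of about one half; that factor is folded
        into the bound, so ``cfl`` is the fraction of the admissible step.
        """
        u_col_max = np.maximum(np.max(self.u_m, axis=0), 1e-300)
        dt_adv = 0.5 * float(np.min(self.dz_m / u_col_max[1:]))
        dt = cfl * dt_adv
        if self.alpha > 0.0:
            dt = min(dt, 0.9 * float(np.min(self.dz_m)) ** 2 / (2.0 * self.alpha))
        return dt

    def _advect(self, T: np.ndarray) -> np.ndarray:
        """Axial advection term -u dT/dz by limited (van Leer / MUSCL)
        second-order upwind reconstruction; flow is always toward +z."""
        dT = T[:, 1:] - T[:, :-1]  # difference across face j+1/2
        # van Leer limited half-increment: harmonic mean of adjacent slopes
        num = dT[:, :-1] * dT[:, 1:]
        den = dT[:, :-1] + dT[:, 1:]
        limited = np.where(num > 0.0, num / np.where(den == 0.0, 1.0, den), 0.0)
        T_face = T[:, :-1].copy()  # upwind value at each face
        T_face[:, 1:] += limited  # second-order correction away from extrema
        out = np.zeros_like(T)
        out[:, 1:-1] = -self.u_m[:, 1:-1] * (T_face[:, 1:] - T_face[:, :-1]) \
            / self.dzc_m[1:-1]
        # outflow column: first-order upwind
        out[:, -1] = -self.u_m[:, -1] * (T[:, -1] - T[:, -2]) / self.dz_m[-1]
        return out

    def step(self, T: np.ndarray, wall_T: float) -> np.ndarray:
        """Advance the temperature field by dt; returns a new array."""
        cond = self.conditions
        dt = self.dt
        rhs = T + dt * self._advect(T)
        # explicit axial diffusion on the nonuniform grid (interior stations)
        if self.alpha > 0.0:
            dzm = self.dz_m[:-1]
            dzp = self.dz_m[1:]
            lap = 2.0 * ((T[:, 2:] - T[:, 1:-1]) / dzp
                         - (T[:, 1:-1] - T[:, :-2]) / dzm) / (dzm + dzp)
            rhs[:, 1:-1] += self.alpha * dt * lap
        rhs[:, 0] = cond.initial_material_temperature
        if self.alpha > 0.0:
            # boundary rows of the implicit radial solve
            robin = ~self.jacketed
            rhs[self.nr - 1, self.jacketed] = wall_T
            rhs[self.nr - 1, robin] += (self._wall_G2[robin]
                                        * cond.ambient_temperature)
            T_new = self._solve(rhs)
        else:
            T_new = rhs
        T_new[:, 0] = cond.initial_material_temperature
        return T_new

    def _solve(self, d: np.ndarray) -> np.ndarray:
        a, cp, inv_den = self._a, self._cp, self._inv_den
        nr = self.nr
        dp = np.empty_like(d)
        dp[0] = d[0] * inv_den[0]
        for i in range(1, nr):
            dp[i] = (d[i] - a[i] * dp[i - 1]) * inv_den[i]
        x = np.empty_like(d)
        x[nr - 1] = dp[nr - 1]
        for i in range(nr - 2, -1, -1):
            x[i] = dp[i] - cp[i] * x[i + 1]
        return x


def admissible_dt(fields: FieldState, geometry: ChannelGeometry,
                  conditions: ProcessConditions, material: MaterialProperties,
                  cfl: float = 1.0, h_exterior: float = 0.0) -> float:
    """Largest stable time step (s) for the given fields and grid."""
    stepper = _ThermalStepper(geometry, conditions, material, fields.s,
                              fields.z, fields.u, dt=1.0, h_exterior=h_exterior)
    return stepper.admissible_dt(cfl)


def step_thermal(fields: FieldState, dt: float, geometry: ChannelGeometry,
                 conditions: ProcessConditions, material: MaterialProperties,
                 convection_config: conv.ConvectionConfig | None = None,
                 wall_T: float | None = None,
                 h_exterior: float | None = None) -> FieldState:
    """One explicit-advection / implicit-radial-diffusion thermal step.

    ``wall_T`` is the jacketed-wall temperature for this step (defaults to
    the initial wall temperature); ``h_exterior`` overrides the
    natural-convection film coefficient on the unjacketed exterior.
    The step raises :class:`StabilityError`, naming the admissible dt, if
    ``dt`` violates the advective CFL bound.
    """
    if h_exterior is None:
        h_exterior = _exterior_film_coefficient(geometry, conditions,
                                                convection_config)
    if wall_T is None:
        wall_T = conditions.initial_barrel_wall_temperature
    stepper = _ThermalStepper(geometry, conditions, material, fields.s,
                              fields.z, fields.u, dt, h_exterior)
    dt_max = stepper.admissible_dt(1.0)
    if dt > dt_max:
        raise StabilityError(
            f"dt = {dt:g} s exceeds the stability bound; admissible dt <= "
            f"{dt_max:g} s on this grid")
    T_new = stepper.step(fields.T, wall_T)
    new = compute_flow_fields(geometry, conditions, material, T_new,
                              fields.s, fields.z, time=fields.time + dt)
    return new


@dataclass
class SimulationResult:
    """Time series and field snapshots of one extrusion run.

    ``times`` (s), ``outlet_mean_T`` (degC, area-mean over the outlet
    section), ``delta_p`` (Pa, inlet minus outlet), ``heater_on``,
    ``wall_T`` (degC, jacketed-wall/thermocouple trace).
    """

    times: np.ndarray
    outlet_mean_T: np.ndarray
    delta_p: np.ndarray
    heater_on: np.ndarray
    wall_T: np.ndarray
    snapshots: list = field(default_factory=list)
    final_state: FieldState | None = None
    parameters: dict = field(default_factory=dict)

    def equilibrium_outlet_temperature(self, tail_fraction: float = 0.1) -> float:
        """Mean outlet temperature over the trailing ``tail_fraction`` of the run."""
        n = max(1, int(round(tail_fraction * self.times.size)))
        return float(np.mean(self.outlet_mean_T[-n:]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times,
            "outlet_mean_T_C": self.outlet_mean_T,
            "delta_p_Pa": self.delta_p,
            "heater_on": self.heater_on.astype(int),
            "wall_T_C": self.wall_T,
        })


def run_simulation(geometry: ChannelGeometry, conditions: ProcessConditions,
                   material: MaterialProperties, grid: GridSpec = GridSpec(),
                   duration: float = 600.0, seed: int = 0,
                   convection_config: conv.ConvectionConfig | None = None,
                   thermostat: ThermostatState | None = None,
                   wall_time_constant: float = 30.0,
                   snapshot_times: tuple = ()) -> SimulationResult:
    """Transient extrusion run: quasi-steady flow + thermal stepping + thermostat.

    The jacketed-wall temperature relaxes first-order (time constant
    ``wall_time_constant`` s) toward the jacket set point while the heater is
    on and toward ambient while it is off; the bang-bang thermostat switches
    the heater on the wall thermocouple.  Outlet-section mean temperature,
    inlet–outlet pressure difference and the heater trace are recorded every
    ``grid.record_interval`` seconds; full field snapshots are stored at the
    requested ``snapshot_times`` and at the end of the run.

    The model is deterministic; ``seed`` is stored with the run parameters
    so that randomised callers can log it, but no randomness is used here.
    """
    if duration <= 0:
        raise SimulationError("duration must be > 0")
    thermostat = thermostat or ThermostatState()
    state = initial_state(geometry, conditions, material, grid)
    h_ext = _exterior_film_coefficient(geometry, conditions, convection_config)

    probe = _ThermalStepper(geometry, conditions, material, state.s, state.z,
                            state.u, dt=1.0, h_exterior=h_ext)
    dt = grid.dt if grid.dt is not None else probe.admissible_dt(grid.cfl)
    if dt > probe.admissible_dt(1.0):
        raise StabilityError(
            f"dt = {dt:g} s exceeds the stability bound; admissible dt <= "
            f"{probe.admissible_dt(1.0):g} s on this grid")
    dt = min(dt, wall_time_constant / 5.0)
    stepper = _ThermalStepper(geometry, conditions, material, state.s, state.z,
                              state.u, dt, h_exterior=h_ext)

    T = state.T
    wall_T = conditions.initial_barrel_wall_temperature
    n_steps = int(math.ceil(duration / dt))
    rec_every = max(1, int(round(grid.record_interval / dt)))
    snap_steps = sorted({min(n_steps, max(1, int(round(t_s / dt))))
                         for t_s in snapshot_times})

    times, out_T, dps, heat, walls = [], [], [], [], []

    def record(t_now, T_now, wall_now, heater_now):
        fs = compute_flow_fields(geometry, conditions, material, T_now,
                                 state.s, state.z, time=t_now)
        times.append(t_now)
        out_T.append(fs.outlet_mean_temperature())
        dps.append(float(fs.pressure[0] - fs.pressure[-1]))
        heat.append(heater_now)
        walls.append(wall_now)
        return fs

    record(0.0, T, wall_T, thermostat.heater_on)
    snapshots = []
    fs = None
    for step in range(1, n_steps + 1):
        thermostat = thermostat_step(thermostat, wall_T)
        target = (conditions.jacket_setpoint if thermostat.heater_on
                  else conditions.ambient_temperature)
        wall_T += dt * (target - wall_T) / wall_time_constant
        T = stepper.step(T, wall_T)
        t_now = step * dt
        if step % rec_every == 0 or step == n_steps:
            if not np.all(np.isfinite(T)):
                raise SimulationError(
                    f"temperature field diverged at t = {t_now:.3f} s "
                    f"(dt = {dt:g}, grid {grid.nr}x{state.z.size})")
            fs = record(t_now, T, wall_T, thermostat.heater_on)
        if step in snap_steps:
            snapshots.append(fs if fs is not None and fs.time == t_now else
                             compute_flow_fields(geometry, conditions, material,
                                                 T, state.s, state.z, time=t_now))

    final = fs if fs is not None and fs.time == n_steps * dt else \
        compute_flow_fields(geometry, conditions, material, T, state.s,
                            state.z, time=n_steps * dt)
    if not snapshots or snapshots[-1].time != final.time:
        snapshots.append(final)
    params = {
        "dt_s": dt, "n_steps": n_steps, "nr": grid.nr, "nz": int(state.z.size),
        "h_exterior_W_m2K": h_ext, "wall_time_constant_s": wall_time_constant,
        "seed": seed, "duration_s": duration,
        "inlet_velocity_mm_s": conditions.inlet_velocity,
        "nozzle_diameter_mm": geometry.nozzle_diameter,
    }
    return SimulationResult(
        times=np.asarray(times), outlet_mean_T=np.asarray(out_T),
        delta_p=np.asarray(dps), heater_on=np.asarray(heat, dtype=bool),
        wall_T=np.asarray(walls), snapshots=snapshots, final_state=final,
        parameters=params)
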