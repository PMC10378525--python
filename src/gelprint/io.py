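"""Delimited-table and configuration IO.

Tables are plain text with a header row, optional ``#`` comment lines
(units are documented there) and comma or tab delimiters.  Column names
carry their units (``shear_rate_1_s``, ``viscosity_Pa_s``, ``width_mm``) so
values cannot silently change units between modules; columns may appear in
any order.  Run configurations are YAML files with sections
geometry / material / conditions / grid / thermostat / convection /
deposition, every key optional with defaults equal to the reference
printer's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .convection import ConvectionConfig
from .flow import ChannelGeometry
from .rheology import (
    OscillatorySweep,
    PowerLawModel,
    RheogramPoint,
    RheologySweep,
    ThermalRamp,
)
from .simulator import GridSpec, MaterialProperties, ProcessConditions, ThermostatState
from .deposition import WidthMeasurement

__all__ = [
    "SchemaError",
    "TableFormatError",
    "TableSchema",
    "read_table",
    "write_table",
    "RHEOGRAM_SCHEMA",
    "THERMAL_RAMP_SCHEMA",
    "OSCILLATORY_SCHEMA",
    "WIDTHS_SCHEMA",
    "sweep_to_frame",
    "frame_to_sweep",
    "ramp_to_frame",
    "frame_to_ramp",
    "oscillatory_to_frame",
    "frame_to_oscillatory",
    "measurements_to_frame",
    "frame_to_measurements",
    "RunConfig",
    "load_config",
    "resolve_config",
]


class SchemaError(ValueError):
    pass


class TableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class TableSchema:
    """Required and optional column names (units embedded) plus dialect."""

    columns: tuple
    optional: tuple = ()
    units_comment: str = ""
    delimiter: str = ","
    comment_prefix: str = "#"


RHEOGRAM_SCHEMA = TableSchema(
    columns=("shear_rate_1_s", "viscosity_Pa_s"), optional=("stress_Pa",),
    units_comment="shear rate in 1/s, apparent viscosity in Pa.s, stress in Pa")
THERMAL_RAMP_SCHEMA = TableSchema(
    columns=("temperature_C", "viscosity_Pa_s"),
    units_comment="temperature in degC, apparent viscosity in Pa.s")
OSCILLATORY_SCHEMA = TableSchema(
    columns=("temperature_C", "G_storage_Pa", "G_loss_Pa"),
    units_comment="temperature in degC, storage/loss moduli in Pa")
WIDTHS_SCHEMA = TableSchema(
    columns=("inlet_velocity_mm_s", "width_mm"),
    units_comment="inlet velocity in mm/s, measured line width in mm")


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a delimited text table, validating it against ``schema``.

    Blank lines and lines starting with the comment prefix are skipped; the
    delimiter (comma or tab) is sniffed from the header.  Missing required
    columns raise :class:`SchemaError` naming the column; unparsable numbers
    raise :class:`TableFormatError` with the file line number.
    """
    path = Path(path)
    rows, line_nos = [], []
    header = None
    delim = schema.delimiter
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(schema.comment_prefix):
                continue
            if header is None:
                delim = "\t" if ("\t" in line and "," not in line) else ","
                header = [c.strip() for c in line.split(delim)]
                continue
            rows.append([c.strip() for c in line.split(delim)])
            line_nos.append(line_no)
    if header is None:
        raise TableFormatError(f"{path}: no header row found")
    missing = [c for c in schema.columns if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    keep = [c for c in header if c in schema.columns + schema.optional]
    data = {c: [] for c in keep}
    for row, line_no in zip(rows, line_nos):
        if len(row) != len(header):
            raise TableFormatError(
                f"{path}:{line_no}: expected {len(header)} fields, got {len(row)}")
        for name, value in zip(header, row):
            if name not in data:
                continue
            try:
                data[name].append(float(value))
            except ValueError:
                raise TableFormatError(
                    f"{path}:{line_no}: cannot parse {value!r} in column {name!r}"
                ) from None
    # canonical column order: required first, then whichever optionals appear
    order = [c for c in schema.columns + schema.optional if c in data]
    return pd.DataFrame({c: np.asarray(data[c]) for c in order})


def write_table(path, frame: pd.DataFrame, schema: TableSchema | None = None) -> None:
    """Write a DataFrame as a delimited table with a units comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if schema is not None and schema.units_comment:
            fh.write(f"# {schema.units_comment}\n")
        frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# conversions between domain types and table frames

def sweep_to_frame(sweep: RheologySweep) -> pd.DataFrame:
    return pd.DataFrame({
        "shear_rate_1_s": sweep.shear_rates,
        "viscosity_Pa_s": sweep.viscosities,
    })


def frame_to_sweep(frame: pd.DataFrame, temperature: float = 25.0,
                   concentration: float = 9.0) -> RheologySweep:
    stress = frame["stress_Pa"] if "stress_Pa" in frame else [None] * len(frame)
    points = tuple(
        RheogramPoint(shear_rate=g, viscosity=e,
                      stress=None if s is None or pd.isna(s) else s)
        for g, e, s in zip(frame["shear_rate_1_s"], frame["viscosity_Pa_s"], stress))
    return RheologySweep(temperature=temperature, concentration=concentration,
                         points=points)


def ramp_to_frame(ramp: ThermalRamp) -> pd.DataFrame:
    return pd.DataFrame({"temperature_C": ramp.temperatures,
                         "viscosity_Pa_s": ramp.viscosities})


def frame_to_ramp(frame: pd.DataFrame) -> ThermalRamp:
    return ThermalRamp(temperatures=frame["temperature_C"].to_numpy(),
                       viscosities=frame["viscosity_Pa_s"].to_numpy())


def oscillatory_to_frame(osc: OscillatorySweep) -> pd.DataFrame:
    return pd.DataFrame({"temperature_C": osc.temperatures,
                         "G_storage_Pa": osc.storage_modulus,
                         "G_loss_Pa": osc.loss_modulus})


def frame_to_oscillatory(frame: pd.DataFrame) -> OscillatorySweep:
    return OscillatorySweep(temperatures=frame["temperature_C"].to_numpy(),
                            storage_modulus=frame["G_storage_Pa"].to_numpy(),
                            loss_modulus=frame["G_loss_Pa"].to_numpy())


def measurements_to_frame(measurements) -> pd.DataFrame:
    ms = list(measurements)
    return pd.DataFrame({
        "inlet_velocity_mm_s": [m.inlet_velocity for m in ms],
        "width_mm": [m.measured_width for m in ms],
    })


def frame_to_measurements(frame: pd.DataFrame) -> list:
    return [WidthMeasurement(inlet_velocity=v, measured_width=w)
            for v, w in zip(frame["inlet_velocity_mm_s"], frame["width_mm"])]


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Fully resolved simulation configuration (all defaults applied)."""

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    material: MaterialProperties = field(
        default_factory=lambda: MaterialProperties(
            rheology=PowerLawModel(k=5.0, n=0.45, T_ref=25.0, b=0.12)))
    conditions: ProcessConditions = field(default_factory=ProcessConditions)
    grid: GridSpec = field(default_factory=GridSpec)
    thermostat: ThermostatState = field(default_factory=ThermostatState)
    convection: ConvectionConfig | None = None
    duration: float = 600.0
    wall_time_constant: float = 30.0
    snapshot_times: tuple = ()

    def to_log_lines(self) -> list[str]:
        lines = []
        for section in ("geometry", "material", "conditions", "grid", "thermostat"):
            obj = getattr(self, section)
            for key, val in vars(obj).items():
                lines.append(f"{section}.{key} = {val}")
        if self.convection is not None:
            for key, val in vars(self.convection).items():
                lines.append(f"convection.{key} = {val}")
        lines.append(f"run.duration = {self.duration}")
        lines.append(f"run.wall_time_constant = {self.wall_time_constant}")
        lines.append(f"run.snapshot_times = {list(self.snapshot_times)}")
        return lines


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping of sections")
    return raw


def _build(cls, section: dict, name: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise SchemaError(f"config section '{name}': {exc}") from None


def resolve_config(raw: dict) -> RunConfig:
    """Apply defaults to a raw config mapping and build typed sections."""
    known = {"geometry", "material", "conditions", "grid", "thermostat",
             "convection", "run"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    material_raw = dict(raw.get("material", {}))
    rheo = _build(PowerLawModel, material_raw.pop("rheology", {"k": 5.0, "n": 0.45, "T_ref": 25.0, "b": 0.12}), "material.rheology")
    conv_raw = raw.get("convection")
    if conv_raw is not None:
        conv_raw = dict(conv_raw)
        if "characteristic_length_m" in conv_raw:
            conv_raw["L"] = conv_raw.pop("characteristic_length_m")
        conv_raw.pop("ambient_temperature_C", None)
    run_raw = dict(raw.get("run", {}))
    conditions_raw = dict(raw.get("conditions", {}))
    if "convection" in raw and raw["convection"] is not None:
        amb = raw["convection"].get("ambient_temperature_C")
        if amb is not None:
            conditions_raw.setdefault("ambient_temperature", amb)
    return RunConfig(
        geometry=_build(ChannelGeometry, raw.get("geometry", {}), "geometry"),
        material=_build(MaterialProperties, {"rheology": rheo, **material_raw},
                        "material"),
        conditions=_build(ProcessConditions, conditions_raw, "conditions"),
        grid=_build(GridSpec, raw.get("grid", {}), "grid"),
        thermostat=_build(ThermostatState, raw.get("thermostat", {}), "thermostat"),
        convection=_build(ConvectionConfig, conv_raw, "convection")
        if conv_raw is not None else None,
        duration=float(run_raw.get("duration", 600.0)),
        wall_time_constant=float(run_raw.get("wall_time_constant", 30.0)),
        snapshot_times=tuple(run_raw.get("snapshot_times", ())),
    )
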