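"""Run configuration: unit-annotated YAML parsing, validation, serialization.

The microtubule literature mixes GPa/MPa/kPa and nm/μm freely, so config files
accept quantities either as plain SI numbers or as ``"value unit"`` strings
(e.g. ``E1: 1.5 GPa``, ``R: 12.7 nm``); everything is converted to SI at parse
time.  Unknown keys are rejected with the offending location in the message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import yaml

from .parameters import (
    Environment,
    OrthotropicMaterial,
    PressureModel,
    ShellGeometry,
    DimensionlessGroups,
    derive_groups,
)

__all__ = ["RunConfig", "SweepSpec", "parse_quantity", "load_config", "ConfigError"]

logger = logging.getLogger("mtshell")

_LENGTH_UNITS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}
_PRESSURE_UNITS = {
    "Pa": 1.0,
    "kPa": 1e3,
    "MPa": 1e6,
    "GPa": 1e9,
}


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


def parse_quantity(value, dimension: str, where: str = "") -> float:
    """Convert a config value to SI.

    ``value`` may be a number (taken as SI) or a string ``"1.5 GPa"``;
    ``dimension`` is ``"length"``, ``"pressure"`` or ``"dimensionless"``.
    """
    units = {
        "length": _LENGTH_UNITS,
        "pressure": _PRESSURE_UNITS,
        "dimensionless": {},
    }.get(dimension)
    if units is None:
        raise ValueError(f"unknown dimension {dimension!r}")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        try:
            if len(parts) == 1:
                return float(parts[0])
            if len(parts) == 2 and parts[1] in units:
                return float(parts[0]) * units[parts[1]]
        except ValueError:
            pass
        raise ConfigError(
            f"{where}: cannot parse {value!r} as a {dimension} quantity "
            f"(known units: {sorted(units) or 'none'})"
        )
    raise ConfigError(f"{where}: expected number or 'value unit' string, got {value!r}")


def _take(mapping: dict, where: str, required: tuple[str, ...], optional: tuple[str, ...] = ()):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - set(required) - set(optional)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = [k for k in required if k not in mapping]
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {missing}")
    return mapping


@dataclass(frozen=True)
class SweepSpec:
    """One sweep axis and its grid values (already in SI / dimensionless)."""

    axis: str
    values: tuple[float, ...]

    AXES = ("eta", "Ec", "L_over_R", "E2_over_E1")

    def __post_init__(self) -> None:
        if self.axis not in self.AXES:
            raise ConfigError(f"sweep axis must be one of {self.AXES}, got {self.axis!r}")
        if len(self.values) == 0:
            raise ConfigError("sweep grid must be nonempty")


def _range_spec(values: tuple[int, ...]) -> list[int]:
    """Serialize a mode range: [lo, hi] bounds when contiguous, else explicit."""
    values = tuple(values)
    if values == tuple(range(values[0], values[-1] + 1)):
        return [values[0], values[-1]]
    return list(values)


@dataclass(frozen=True)
class RunConfig:
    """A fully validated shell problem plus solver settings."""

    geometry: ShellGeometry
    material: OrthotropicMaterial
    environment: Environment
    m_range: tuple[int, ...] = tuple(range(1, 6))
    n_range: tuple[int, ...] = tuple(range(0, 9))
    sweep: SweepSpec | None = None
    seed: int = 0

    def groups(self) -> DimensionlessGroups:
        return derive_groups(self.geometry, self.material, self.environment)

    def with_axis_value(self, axis: str, value: float) -> "RunConfig":
        """A copy of this config with one sweep-axis value applied."""
        if axis == "eta":
            env = replace(self.environment, ea0=float(value) * self.geometry.R)
            return replace(self, environment=env)
        if axis == "Ec":
            env = replace(self.environment, Ec=float(value), sigma=None)
            return replace(self, environment=env)
        if axis == "L_over_R":
            geom = replace(self.geometry, L=float(value) * self.geometry.R)
            return replace(self, geometry=geom)
        if axis == "E2_over_E1":
            mat = replace(self.material, E2=float(value) * self.material.E1)
            return replace(self, material=mat)
        raise ConfigError(f"unknown sweep axis {axis!r}")

    def to_dict(self) -> dict:
        """Plain-SI dictionary; parsing it back yields an identical config."""
        g, m, e = self.geometry, self.material, self.environment
        d: dict = {
            "geometry": {"L": g.L, "R": g.R, "h": g.h, "h0": g.h0},
            "material": {"E1": m.E1, "E2": m.E2, "G": m.G, "mu1": m.mu1, "mu2": m.mu2},
            "environment": {
                "Ec": e.Ec,
                "ea0": e.ea0,
                "pressure": {"model": e.pressure.kind},
            },
            "modes": {
                "m_range": _range_spec(self.m_range),
                "n_range": _range_spec(self.n_range),
            },
            "seed": self.seed,
        }
        if e.sigma is not None:
            d["environment"]["sigma"] = e.sigma
        if e.pressure.kind == "constant":
            d["environment"]["pressure"]["value"] = e.pressure.value
        if e.pressure.kind == "proportional":
            d["environment"]["pressure"]["kappa"] = e.pressure.kappa
        if self.sweep is not None:
            d["sweep"] = {"axis": self.sweep.axis, "values": list(self.sweep.values)}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _parse_pressure(node, where: str) -> PressureModel:
    if node is None:
        return PressureModel.zero()
    _take(node, where, ("model",), ("value", "kappa"))
    model = node["model"]
    if model == "zero":
        return PressureModel.zero()
    if model == "constant":
        if "value" not in node:
            raise ConfigError(f"{where}: constant pressure requires 'value'")
        return PressureModel.constant(parse_quantity(node["value"], "pressure", where))
    if model == "proportional":
        if "kappa" not in node:
            raise ConfigError(f"{where}: proportional pressure requires 'kappa'")
        return PressureModel.proportional(
            parse_quantity(node["kappa"], "pressure", where)
        )
    raise ConfigError(f"{where}: unknown pressure model {model!r}")


def _parse_range(node: dict, key_range: str, key_max: str, lo: int, where: str):
    if key_range in node and key_max in node:
        raise ConfigError(f"{where}: give either {key_range} or {key_max}, not both")
    if key_max in node:
        return tuple(range(lo, int(node[key_max]) + 1))
    if key_range in node:
        values = node[key_range]
        if len(values) == 2:  # inclusive bounds [lo, hi]
            a, b = values
            return tuple(range(int(a), int(b) + 1))
        return tuple(sorted(int(v) for v in values))  # explicit mode list
    return None


def from_dict(data: dict) -> RunConfig:
    """Validate a configuration dictionary (as loaded from YAML) into a RunConfig."""
    _take(
        data, "config",
        ("geometry", "material"),
        ("environment", "modes", "sweep", "seed"),
    )
    gnode = _take(data["geometry"], "geometry", ("L", "R", "h", "h0"))
    geometry = ShellGeometry(
        **{k: parse_quantity(gnode[k], "length", f"geometry.{k}") for k in ("L", "R", "h", "h0")}
    )
    mnode = _take(data["material"], "material", ("E1", "E2", "G", "mu1", "mu2"))
    material = OrthotropicMaterial(
        E1=parse_quantity(mnode["E1"], "pressure", "material.E1"),
        E2=parse_quantity(mnode["E2"], "pressure", "material.E2"),
        G=parse_quantity(mnode["G"], "pressure", "material.G"),
        mu1=parse_quantity(mnode["mu1"], "dimensionless", "material.mu1"),
        mu2=parse_quantity(mnode["mu2"], "dimensionless", "material.mu2"),
    )
    enode = data.get("environment") or {}
    _take(enode, "environment", (), ("Ec", "sigma", "ea0", "pressure"))
    sigma = None
    if "sigma" in enode:
        sigma = parse_quantity(enode["sigma"], "pressure", "environment.sigma")
    environment = Environment(
        Ec=parse_quantity(enode.get("Ec", 0.0), "pressure", "environment.Ec"),
        sigma=sigma,
        ea0=parse_quantity(enode.get("ea0", 0.0), "length", "environment.ea0"),
        pressure=_parse_pressure(enode.get("pressure"), "environment.pressure"),
    )
    if sigma is not None and environment.Ec > 0.0:
        logger.warning(
            "environment: explicit foundation constant sigma=%g Pa overrides "
            "the Ec-derived value %g Pa",
            sigma, 2.7 * environment.Ec,
        )
    mode_node = data.get("modes") or {}
    _take(mode_node, "modes", (), ("m_range", "m_max", "n_range", "n_max"))
    m_range = _parse_range(mode_node, "m_range", "m_max", 1, "modes") or tuple(range(1, 6))
    n_range = _parse_range(mode_node, "n_range", "n_max", 0, "modes") or tuple(range(0, 9))
    sweep = None
    if "sweep" in data and data["sweep"] is not None:
        snode = _take(data["sweep"], "sweep", ("axis", "values"))
        dim = "pressure" if snode["axis"] == "Ec" else "dimensionless"
        sweep = SweepSpec(
            axis=snode["axis"],
            values=tuple(
                parse_quantity(v, dim, "sweep.values") for v in snode["values"]
            ),
        )
    return RunConfig(
        geometry=geometry,
        material=material,
        environment=environment,
        m_range=m_range,
        n_range=n_range,
        sweep=sweep,
        seed=int(data.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return from_dict(data)
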