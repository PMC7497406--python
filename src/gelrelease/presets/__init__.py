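"""Packaged configurations and the structured-text (TOML) config loader."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

from ..experiment import ExchangeProtocol
from ..solver import SolverConfig, WellGeometry
from ..transport import TransportParams

__all__ = [
    "RunSetup",
    "ConfigError",
    "load_configuration",
    "reference_configuration",
]

HOUR_S = 3600.0


class ConfigError(ValueError):
    """Malformed configuration: lists every offending key."""


@dataclass
class RunSetup:
    """Fully resolved inputs for one release simulation."""

    params: TransportParams
    geometry: WellGeometry
    protocol: ExchangeProtocol
    solver: SolverConfig
    reference: dict

    def to_dict(self) -> dict:
        return {
            "transport": self.params.to_dict(),
            "geometry": self.geometry.to_dict(),
            "protocol": self.protocol.to_dict(),
            "solver": self.solver.to_dict(),
            "reference": dict(self.reference),
        }


_TRANSPORT_KEYS = {
    "temperature_K",
    "viscosity_Pa_s",
    "molecular_weight_g_mol",
    "binder_concentration_kg_m3",
    "binder_diffusivity_m2_s",
    "porosity",
    "bound_fraction",
    "initial_concentration_ng_mL",
}
_GEOMETRY_KEYS = {"cross_section_area_m2", "gel_volume_m3", "media_volume_m3"}
_PROTOCOL_KEYS = {"horizon_h", "exchange_times_h"}
_SOLVER_KEYS = {
    "n_cells_gel",
    "n_cells_media",
    "dt_s",
    "scheme",
    "mass_tolerance",
    "media_mode",
    "perfect_sink",
}


def _check_keys(section: str, data: dict, allowed: set, required: set) -> list[str]:
    problems = []
    for key in sorted(required - set(data)):
        problems.append(f"[{section}] missing required key {key!r}")
    for key in sorted(set(data) - allowed):
        problems.append(f"[{section}] unknown key {key!r}")
    return problems


def load_configuration(path) -> RunSetup:
    """Parse a TOML run configuration into validated domain objects.

    Raises :class:`ConfigError` naming every missing or unknown key at once.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    problems: list[str] = []
    known_sections = {"transport", "geometry", "protocol", "solver", "reference"}
    for section in sorted(set(raw) - known_sections):
        problems.append(f"unknown section [{section}]")
    transport = raw.get("transport", {})
    geometry = raw.get("geometry", {})
    protocol = raw.get("protocol", {})
    solver = raw.get("solver", {})
    problems += _check_keys("transport", transport, _TRANSPORT_KEYS, set())
    problems += _check_keys("geometry", geometry, _GEOMETRY_KEYS, _GEOMETRY_KEYS)
    problems += _check_keys("protocol", protocol, _PROTOCOL_KEYS, set())
    problems += _check_keys("solver", solver, _SOLVER_KEYS, set())
    if problems:
        raise ConfigError("; ".join(problems))

    try:
        params = TransportParams(**transport)
        geom = WellGeometry(**geometry)
        proto = ExchangeProtocol(
            horizon_s=protocol.get("horizon_h", 72.0) * HOUR_S,
            exchange_times_s=tuple(
                t * HOUR_S for t in protocol.get("exchange_times_h", (24, 48, 72))
            ),
        )
        config = SolverConfig(**solver)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return RunSetup(
        params=params,
        geometry=geom,
        protocol=proto,
        solver=config,
        reference=dict(raw.get("reference", {})),
    )


def reference_configuration() -> RunSetup:
    """The packaged reference release assay (12-well, daily exchange)."""
    preset = resources.files(__package__).joinpath("reference.toml")
    with resources.as_file(preset) as path:
        return load_configuration(path)
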