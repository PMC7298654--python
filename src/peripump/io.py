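"""Scenario file parsing and deterministic report writing.

Config files are YAML with SI units baked into the key names
(``length_m``, ``wave_speed_m_s``) so values cannot silently drift units.
Unknown keys are rejected by name; missing blocks fall back to the study
defaults (1 m tube, 1.6 mm inner diameter, Newtonian 1 Pa s fluid) and the
fallback is logged.

Report writing is deterministic: the same report produces byte-identical
JSON/CSV files, and a ``manifest.json`` records the SHA-256 checksum of
every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fluids import GellingViscosity, NewtonianFluid, PowerLawFluid
from .gelation import ClogReport
from .geometry import CascadeConfig, PumpUnit, TubeSpec
from .shear import ShearReport

__all__ = [
    "LoadedScenario",
    "ConfigError",
    "load_config",
    "dump_config",
    "write_report",
]

log = logging.getLogger("peripump")


class ConfigError(ValueError):
    """Schema violation in a scenario file; the message names the key."""


_TUBE_KEYS = {"length_m", "inner_diameter_m", "nodes"}
_PUMP_KEYS = {"center_m", "deformation_length_m", "occlusion", "wave_speed_m_s",
              "phase_rad", "rollers", "capacity_pa"}
_FLUID_KEYS = {
    "newtonian": {"model", "viscosity_pa_s", "density_kg_m3"},
    "power_law": {"model", "consistency_pa_sn", "flow_index", "density_kg_m3"},
    "gelling": {"model", "consistency_pa_sn", "flow_index", "density_kg_m3",
                "plateau_multiplier", "onset_time_s", "rise_time_s"},
}
_SOLVER_KEYS = {"periods", "steps_per_period", "discard_periods"}
_TOP_KEYS = {"tube", "waveform", "pumps", "fluid", "solver", "name"}


@dataclass
class LoadedScenario:
    name: str
    config: CascadeConfig
    fluid: object
    solver: dict


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> LoadedScenario:
    """Parse and validate a YAML scenario file into domain objects."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario file {path} is not a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")

    tube_block = raw.get("tube")
    if tube_block is None:
        log.info("no tube block in %s; using defaults L=1 m, ID=1.6 mm", path)
        tube = TubeSpec()
    else:
        _reject_unknown(tube_block, _TUBE_KEYS, "tube")
        kwargs = {}
        if "length_m" in tube_block:
            kwargs["length"] = float(tube_block["length_m"])
        if "inner_diameter_m" in tube_block:
            kwargs["inner_radius"] = 0.5 * float(tube_block["inner_diameter_m"])
        if "nodes" in tube_block:
            kwargs["nodes"] = int(tube_block["nodes"])
        tube = TubeSpec(**kwargs)

    pumps = []
    for i, block in enumerate(raw.get("pumps", [])):
        _reject_unknown(block, _PUMP_KEYS, f"pumps[{i}]")
        if "center_m" not in block:
            raise ConfigError(f"pumps[{i}] is missing center_m")
        kwargs = {"center": float(block["center_m"])}
        if "deformation_length_m" in block:
            kwargs["deformation_length"] = float(block["deformation_length_m"])
        if "occlusion" in block:
            kwargs["occlusion"] = float(block["occlusion"])
        if "wave_speed_m_s" in block:
            kwargs["wave_speed"] = float(block["wave_speed_m_s"])
        if "phase_rad" in block:
            kwargs["phase"] = float(block["phase_rad"])
        if "rollers" in block:
            kwargs["rollers"] = int(block["rollers"])
        if "capacity_pa" in block:
            kwargs["capacity"] = float(block["capacity_pa"])
        pumps.append(PumpUnit(**kwargs))

    try:
        config = CascadeConfig(tube=tube, pumps=tuple(pumps),
                               waveform=raw.get("waveform", "modulated_bump"))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    fluid_block = raw.get("fluid") or {"model": "newtonian"}
    model = fluid_block.get("model", "newtonian")
    if model not in _FLUID_KEYS:
        raise ConfigError(f"unknown fluid model {model!r} in fluid")
    _reject_unknown(fluid_block, _FLUID_KEYS[model], "fluid")
    if model == "newtonian":
        fluid = NewtonianFluid(
            viscosity=float(fluid_block.get("viscosity_pa_s", 1.0)),
            density=float(fluid_block.get("density_kg_m3", 1000.0)),
        )
    else:
        base = PowerLawFluid(
            consistency=float(fluid_block.get("consistency_pa_sn", 1.0)),
            flow_index=float(fluid_block.get("flow_index", 0.8)),
            density=float(fluid_block.get("density_kg_m3", 1000.0)),
        )
        if model == "power_law":
            fluid = base
        else:
            fluid = GellingViscosity(
                base=base,
                plateau_multiplier=float(fluid_block.get("plateau_multiplier", 50.0)),
                onset_time=float(fluid_block.get("onset_time_s", 600.0)),
                rise_time=float(fluid_block.get("rise_time_s", 120.0)),
            )

    solver_block = raw.get("solver") or {}
    _reject_unknown(solver_block, _SOLVER_KEYS, "solver")
    solver = {
        "periods": int(solver_block.get("periods", 5)),
        "steps_per_period": int(solver_block.get("steps_per_period", 64)),
        "discard_periods": int(solver_block.get("discard_periods", 3)),
    }
    return LoadedScenario(name=str(raw.get("name", path.stem)), config=config,
                          fluid=fluid, solver=solver)


def dump_config(scenario: LoadedScenario) -> dict:
    """Normalized dict form of a scenario (inverse of :func:`load_config`)."""
    cfg = scenario.config
    fluid = scenario.fluid
    if isinstance(fluid, NewtonianFluid):
        fluid_block = {"model": "newtonian", "viscosity_pa_s": fluid.viscosity,
                       "density_kg_m3": fluid.density}
    elif isinstance(fluid, PowerLawFluid):
        fluid_block = {"model": "power_law", "consistency_pa_sn": fluid.consistency,
                       "flow_index": fluid.flow_index,
                       "density_kg_m3": fluid.density}
    elif isinstance(fluid, GellingViscosity):
        fluid_block = {"model": "gelling",
                       "consistency_pa_sn": fluid.base.consistency,
                       "flow_index": fluid.base.flow_index,
                       "density_kg_m3": fluid.base.density,
                       "plateau_multiplier": fluid.plateau_multiplier,
                       "onset_time_s": fluid.onset_time,
                       "rise_time_s": fluid.rise_time}
    else:
        raise TypeError(f"cannot serialize fluid {type(fluid).__name__}")
    pumps = []
    for p in cfg.pumps:
        block = {"center_m": p.center, "deformation_length_m": p.deformation_length,
                 "occlusion": p.occlusion, "wave_speed_m_s": p.wave_speed,
                 "phase_rad": p.phase, "rollers": p.rollers}
        if p.capacity is not None:
            block["capacity_pa"] = p.capacity
        pumps.append(block)
    return {
        "name": scenario.name,
        "tube": {"length_m": cfg.tube.length,
                 "inner_diameter_m": 2.0 * cfg.tube.inner_radius,
                 "nodes": cfg.tube.nodes},
        "waveform": cfg.waveform,
        "pumps": pumps,
        "fluid": fluid_block,
        "solver": dict(scenario.solver),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def write_report(report, out_dir) -> dict:
    """Write a report to ``out_dir`` and return the file manifest.

    Accepts a :class:`~peripump.shear.ShearReport`, a
    :class:`~peripump.gelation.ClogReport`, or a plain dict (written as the
    summary alone).  All numbers are serialized at full precision and the
    output is deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(report, ShearReport):
        _write_json(report.to_dict(), out / "shear_summary.json")
        written.append(out / "shear_summary.json")
        for pump in report.pumps:
            for plane, hist in (("xy", pump.hist_xy), ("yz", pump.hist_yz)):
                p = out / f"histogram_{plane}_pump{pump.pump_index}.csv"
                _write_csv(hist.to_frame(), p)
                written.append(p)
        prof = {p.name: p for p in report.profiles}
        frame = pd.DataFrame({
            "x_m": report.summary.x,
            "mean_pressure_pa": prof["pressure_mean"].value,
            "peak_pressure_pa": prof["pressure_peak"].value,
        })
        _write_csv(frame, out / "pressure_profile.csv")
        written.append(out / "pressure_profile.csv")
        frame = pd.DataFrame({
            "x_m": report.summary.x,
            "mean_flow_m3_s": prof["flow_mean"].value,
            "peak_flow_m3_s": prof["flow_peak"].value,
        })
        _write_csv(frame, out / "flow_profile.csv")
        written.append(out / "flow_profile.csv")
    elif isinstance(report, ClogReport):
        payload = {
            "n_pumps": len(report.config.pumps),
            "capacities_pa": list(map(float, report.capacities)),
            "target_flow_m3_s": report.target_flow,
            "clog_time_s": report.clog_time,
            "clogged": report.clogged,
            "sustained_fraction": report.sustained_fraction(),
            "peak_load_fractions": list(map(float, report.load_fraction())),
            "warning": report.warning,
        }
        _write_json(payload, out / "clog_report.json")
        written.append(out / "clog_report.json")
        frame = pd.DataFrame({
            "t_s": report.t,
            "flow_m3_s": report.flow,
            "demand_pa": report.demand,
        })
        _write_csv(frame, out / "flow_timeseries.csv")
        written.append(out / "flow_timeseries.csv")
    elif isinstance(report, dict):
        _write_json(report, out / "summary.json")
        written.append(out / "summary.json")
    else:
        raise TypeError(f"cannot write report of type {type(report).__name__}")

    manifest = {
        "files": {
            p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(written)
        }
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
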