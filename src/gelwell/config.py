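"""Flat key-value run configuration with the model defaults.

Keys at the config/CLI boundary use human-scale units (um, uM, seconds);
they are converted to SI when the domain objects are built.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .core_model import (
    AnnealingSchedule,
    GelParams,
    InterfaceModel,
    MotifSpec,
    PhysicalParams,
    WellGeometry,
    make_well_geometry,
)

__all__ = ["DEFAULTS", "load_config", "build_model_inputs"]

DEFAULTS: dict[str, Any] = {
    "temperature_K": 298.0,
    "viscosity_Pa_s": 1e-2,
    "motif_radius_nm": 5.0,
    "interface_thickness_nm": 40.0,
    "gel_motif_concentration_uM": 14.0,
    "compaction_factor": 5.0,
    "well_diameters_um": [50.0, 100.0],
    "well_depth_um": 100.0,
    "interface_model": "disc_at_mouth",
    "contact_angle_deg": 0.0,
    "concentrations_uM": [1.0, 4.0, 8.0],
    "n_rounds": 1,
    "hot_temperature_K": 348.15,
    "hold_seconds": 60.0,
    "cool_seconds": 180.0,
    "cooling_time_constant_s": 30.0,
    "ambient_temperature_K": 298.0,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Defaults overlaid with the JSON file at *path* (if given)."""
    cfg = dict(DEFAULTS)
    if path is not None:
        user = json.loads(Path(path).read_text())
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def build_model_inputs(cfg: dict[str, Any]):
    """Convert a flat config into the domain objects of the kinetic model."""
    import math

    phys = PhysicalParams(
        temperature=cfg["temperature_K"], viscosity=cfg["viscosity_Pa_s"]
    )
    motif = MotifSpec(hydrodynamic_radius=cfg["motif_radius_nm"] * 1e-9)
    gel = GelParams(
        gel_motif_concentration=cfg["gel_motif_concentration_uM"] * 1e-6,
        compaction_factor=cfg["compaction_factor"],
    )
    wells: list[WellGeometry] = [
        make_well_geometry(
            diameter=d * 1e-6,
            depth=cfg["well_depth_um"] * 1e-6,
            interface_thickness=cfg["interface_thickness_nm"] * 1e-9,
            interface_model=InterfaceModel(cfg["interface_model"]),
            contact_angle=math.radians(cfg["contact_angle_deg"]),
        )
        for d in cfg["well_diameters_um"]
    ]
    concentrations = [c * 1e-6 for c in cfg["concentrations_uM"]]
    schedule = AnnealingSchedule(
        n_rounds=int(cfg["n_rounds"]),
        hot_temperature=cfg["hot_temperature_K"],
        hold_seconds=cfg["hold_seconds"],
        cool_seconds=cfg["cool_seconds"],
        cooling_time_constant=cfg["cooling_time_constant_s"],
        ambient_temperature=cfg["ambient_temperature_K"],
    )
    return phys, motif, gel, wells, concentrations, schedule
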