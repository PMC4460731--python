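"""YAML/JSON configuration loading for the CLI.

A config file has up to four blocks::

    coil:
      inner_diameter_m: 3.0e-3
      outer_diameter_m: 1.4e-2
      length_m: 0.105
      n_layers: 35
      turns_per_layer: 159
      wire_bare_m: 0.202e-3
      wire_insulated_m: 0.268e-3
      measured_R_ohm: 50.45
      measured_L_H: 14.25e-3
      calibration_mode: match_L        # none | match_R | match_L
    waveform:
      kind: sawtooth                   # sawtooth | triangle | sine
      vpp: 20.0
      offset_v: 0.0
      freq_hz: 1.0e5
      fall_time_s: 50.0e-9
    circuit:
      source_ohm: 50.0
      coil_R_ohm: 50.45
      coil_L_H: 14.25e-3
      coil_Cp_F: 0.0
    assay:
      transwell:
        side: north
        well_z_m: [-0.03, 0.0, 0.03]
        rho_span_m: [9.0e-3, 15.5e-3]
      plate:
        offset_m: 1.0e-3
        region_m: [1.0e-2, 1.0e-2]
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .assay_geometry import PlateConfig, TranswellConfig
from .coil_model import CoilSpec
from .drive_circuit import CircuitModel, Waveform

__all__ = [
    "load_config",
    "coil_from_config",
    "waveform_from_config",
    "circuit_from_config",
    "transwell_from_config",
    "plate_from_config",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def coil_from_config(cfg: dict) -> tuple[CoilSpec, str]:
    c = cfg["coil"]
    spec = CoilSpec(
        inner_diameter=float(c["inner_diameter_m"]),
        outer_diameter=float(c["outer_diameter_m"]),
        coil_length=float(c["length_m"]),
        n_layers=int(c["n_layers"]),
        turns_per_layer=int(c["turns_per_layer"]),
        wire_diameter_bare=float(c["wire_bare_m"]),
        wire_diameter_insulated=float(c["wire_insulated_m"]),
        measured_resistance=(
            float(c["measured_R_ohm"]) if c.get("measured_R_ohm") is not None else None
        ),
        measured_inductance=(
            float(c["measured_L_H"]) if c.get("measured_L_H") is not None else None
        ),
    )
    return spec, str(c.get("calibration_mode", "none"))


def waveform_from_config(cfg: dict) -> Waveform:
    w = cfg["waveform"]
    return Waveform(
        kind=str(w.get("kind", "sawtooth")),
        peak_to_peak=float(w.get("vpp", 0.0)),
        dc_offset=float(w.get("offset_v", 0.0)),
        period=1.0 / float(w["freq_hz"]),
        fall_time=float(w.get("fall_time_s", 0.0)),
    )


def circuit_from_config(cfg: dict) -> CircuitModel:
    c = cfg["circuit"]
    return CircuitModel(
        source_impedance=float(c.get("source_ohm", 50.0)),
        coil_resistance=float(c["coil_R_ohm"]),
        coil_inductance=float(c["coil_L_H"]),
        coil_capacitance=float(c.get("coil_Cp_F", 0.0)),
    )


def transwell_from_config(cfg: dict) -> TranswellConfig:
    t = cfg["assay"]["transwell"]
    return TranswellConfig(
        well_axial_centers=tuple(float(z) for z in t["well_z_m"]),
        membrane_radial_span=tuple(float(r) for r in t["rho_span_m"]),
        side=str(t.get("side", "north")),
        winding_handedness=int(t.get("winding_handedness", -1)),
    )


def plate_from_config(cfg: dict) -> PlateConfig:
    p = cfg["assay"]["plate"]
    return PlateConfig(
        plate_bottom_offset=float(p["offset_m"]),
        region=tuple(float(r) for r in p.get("region_m", (1e-2, 1e-2))),
    )
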