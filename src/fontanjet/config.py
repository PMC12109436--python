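"""YAML (de)serialization of the model/analysis configuration.

Schema (all keys optional except ``compartments``)::

    pump: {heart_rate, stroke_volume, ejection_fraction_of_cycle}
    venous_reference_pressure: mmHg
    systemic_split_target: fraction
    pulmonary_split_target: fraction
    plumbing: {aortic_compliance, venous_resistance, drain_resistance}
    compartments:
      upper_systemic: {resistance, compliance}   # mmHg.min/L, mL/mmHg
      lower_systemic: {...}
      rpa: {...}
      lpa: {...}
    filter: {butterworth_order, butterworth_cutoff, sg_window, sg_polyorder}
    sensor: {sampling_rate, flow_noise_sd, pressure_noise_sd,
             mains_frequency, mains_amplitude_flow, mains_amplitude_pressure}
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError
from .lpm_core import (COMPARTMENT_NAMES, LPMParameters, PlumbingSettings,
                       PumpSettings, WindkesselCompartment)


def _default_config_path() -> Path:
    return Path(str(resources.files("fontanjet").joinpath("data/default_lpm.yaml")))


def parameters_from_dict(doc: dict) -> LPMParameters:
    try:
        comps = tuple(
            WindkesselCompartment(name,
                                  float(doc["compartments"][name]["resistance"]),
                                  float(doc["compartments"][name]["compliance"]))
            for name in COMPARTMENT_NAMES)
    except KeyError as exc:
        raise ConfigError(f"missing compartment entry: {exc}") from exc
    pump = PumpSettings(**{k: float(v) for k, v in doc.get("pump", {}).items()})
    plumbing = PlumbingSettings(**{k: float(v) for k, v in doc.get("plumbing", {}).items()})
    return LPMParameters(
        compartments=comps, pump=pump,
        venous_reference_pressure=float(doc.get("venous_reference_pressure", 5.0)),
        systemic_split_target=float(doc.get("systemic_split_target", 0.30)),
        pulmonary_split_target=float(doc.get("pulmonary_split_target", 0.50)),
        plumbing=plumbing)


def parameters_to_dict(params: LPMParameters) -> dict:
    return {
        "pump": {"heart_rate": params.pump.heart_rate,
                 "stroke_volume": params.pump.stroke_volume,
                 "ejection_fraction_of_cycle": params.pump.ejection_fraction_of_cycle},
        "venous_reference_pressure": params.venous_reference_pressure,
        "systemic_split_target": params.systemic_split_target,
        "pulmonary_split_target": params.pulmonary_split_target,
        "plumbing": {"aortic_compliance": params.plumbing.aortic_compliance,
                     "venous_resistance": params.plumbing.venous_resistance,
                     "drain_resistance": params.plumbing.drain_resistance},
        "compartments": {c.name: {"resistance": c.resistance,
                                  "compliance": c.compliance}
                         for c in params.compartments},
    }


def load_parameters_yaml(path: str | Path) -> LPMParameters:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return parameters_from_dict(doc)


def save_parameters_yaml(params: LPMParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(parameters_to_dict(params), sort_keys=False))
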