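"""YAML configuration files mirroring the parameter table.

A config file has up to four sections::

    preset: default          # optional named base (see experiments)
    network:                 # NetworkConfig fields
      N: 500
      g: 8
    plasticity:              # PlasticityParams fields
      A_LTP: 8.0e-5
      rule_IE: voltage
      vogels: {eta: 0.1, alpha: 0.01}
    input:                   # InputParams fields
      s_b: 2.0

Fields not given fall back to the preset (or the defaults).  Unknown
keys are rejected so parameter typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .network import NetworkConfig
from .plasticity import PlasticityParams, VogelsParams
from .stimuli import InputParams

__all__ = ["load_config"]


def _update(obj, section: dict, name: str):
    known = {f.name for f in fields(obj)}
    unknown = set(section) - known
    if unknown:
        raise KeyError(f"unknown {name} keys: {sorted(unknown)}")
    return replace(obj, **section)


def load_config(path):
    """Read a YAML file into an ExperimentSpec."""
    from .experiments import ExperimentSpec, get_preset

    doc = yaml.safe_load(Path(path).read_text()) or {}
    spec = get_preset(doc.pop("preset")) if "preset" in doc \
        else ExperimentSpec()
    if "network" in doc:
        net = _update(spec.network, doc.pop("network"), "network")
        net.validate()
        spec = spec.copy(network=net)
    if "plasticity" in doc:
        sec = dict(doc.pop("plasticity"))
        if "vogels" in sec and isinstance(sec["vogels"], dict):
            sec["vogels"] = VogelsParams(**sec["vogels"])
        pl = spec.plasticity or PlasticityParams()
        spec = spec.copy(plasticity=_update(pl, sec, "plasticity"))
    if "input" in doc:
        ip = _update(spec.input_params, doc.pop("input"), "input")
        ip.validate()
        spec = spec.copy(input_params=ip)
    spec_fields = {f.name for f in fields(spec)}
    extra = set(doc) - spec_fields
    if extra:
        raise KeyError(f"unknown config keys: {sorted(extra)}")
    if doc:
        spec = spec.copy(**doc)
    return spec
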