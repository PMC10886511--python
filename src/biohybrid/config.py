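"""YAML configuration loading for the simulator's parameter dataclasses.

A config file holds one mapping per component; unknown keys are rejected so
typos fail loudly::

    encoder:
      k_sa: 6.0
      k_ra: 0.5
    neuron:
      a: 0.1
      dt: 0.5
    decoder:
      v_thresh: 75.0
    plant:
      servo_tau_ms: 25.0
    culture:
      noise_rms: 15.0
"""

from __future__ import annotations

import dataclasses

import yaml

from .culture import CultureConfig
from .decoding import DecoderConfig
from .encoding import EncoderGains, IzhikevichParams
from .plant import PlantConfig

__all__ = ["SECTIONS", "load_config", "dump_config"]

SECTIONS = {
    "encoder": EncoderGains,
    "neuron": IzhikevichParams,
    "decoder": DecoderConfig,
    "plant": PlantConfig,
    "culture": CultureConfig,
}


def load_config(path) -> dict:
    """Read a YAML file into a dict of constructed config dataclasses.

    Sections absent from the file get their defaults; returns
    ``{section: dataclass instance}`` for every known section.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for name, cls in SECTIONS.items():
        kwargs = raw.get(name, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(kwargs) - valid
        if bad:
            raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
        out[name] = cls(**kwargs)
    return out


def dump_config(configs: dict, path) -> None:
    """Write config dataclasses back out as YAML."""
    doc = {name: dataclasses.asdict(cfg) for name, cfg in configs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
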