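"""Load simulation configurations from YAML key/value files.

Example
-------
::

    seed: 7
    n_samples: 11
    groups: {tumor: 6, healthy: 5}
    n_replicates: 4
    methods:
      - {label: capture_release, bias: 1.0, replicate_cv: 0.08}
      - {label: ultracentrifugation, bias: 0.9, replicate_cv: 0.12}
    assays:
      - {label: protein_total, log_mean: 5.0, log_sd: 0.5}
    nta:
      n_particles: 500
      components:
        - {weight: 0.7, log_mean: 4.55, log_sd: 0.25}
        - {weight: 0.3, log_mean: 5.14, log_sd: 0.20}

Omitted ``methods``/``assays`` fall back to the package defaults.
"""

from __future__ import annotations

import os

import yaml

from .datamodel import ConfigError
from .simulate import (
    AssaySpec,
    LognormalComponent,
    MethodSpec,
    NTAConfig,
    SimulationConfig,
    default_assays,
    default_methods,
)


def config_from_mapping(data: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        methods = (
            tuple(MethodSpec(**m) for m in data["methods"])
            if "methods" in data
            else default_methods()
        )
        assays = (
            tuple(AssaySpec(**a) for a in data["assays"])
            if "assays" in data
            else default_assays()
        )
        nta = None
        if data.get("nta") is not None:
            nta_data = dict(data["nta"])
            if "components" in nta_data:
                nta_data["components"] = tuple(
                    LognormalComponent(**c) for c in nta_data["components"]
                )
            nta = NTAConfig(**nta_data)
        cfg = SimulationConfig(
            methods=methods,
            assays=assays,
            n_samples=int(data.get("n_samples", 11)),
            groups=dict(data.get("groups", {"tumor": 6, "healthy": 5})),
            n_replicates=int(data.get("n_replicates", 4)),
            nta=nta,
            seed=int(data.get("seed", 0)),
        )
    except (TypeError, KeyError, ValueError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc
    cfg.validate()
    return cfg


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Read a YAML simulation config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_mapping(data or {})
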