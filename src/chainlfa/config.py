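"""Structured configuration files.

A config is a YAML mapping with up to two sections, ``micro`` and
``membrane``, whose keys are exactly the global-parameter symbol names of the
two models (``L_chain``, ``k_on``, ..., ``N_Abs``, ``k_recruit``, ...).
Unknown sections or keys are hard errors; an empty config reproduces the
default parameter tables bit-exactly.  Light magnitude sanity bounds catch
unit slips (e.g. a chain length given in micrometres instead of metres).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .parameters import MembraneModelParams, MicroModelParams

#: (lower, upper) magnitude sanity bounds for selected keys, SI units.
_SANITY: dict[str, tuple[float, float]] = {
    "L_chain": (1e-8, 1e-4),
    "W_chain": (1e-9, 1e-4),
    "domain_size": (1e-7, 1e-2),
    "mu_fluid": (1e-5, 10.0),
    "eta_fluid": (1e-5, 10.0),
    "L_model": (1e-5, 1.0),
    "H_membrane": (1e-5, 1.0),
    "pore_size": (1e-8, 1e-2),
    "gamma_surface": (1e-4, 1.0),
}


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


def _build(cls, section: str, data: dict[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}; "
            f"valid keys are {sorted(valid)}"
        )
    for key, value in data.items():
        if not isinstance(value, (int, float)):
            raise ConfigError(f"{section}.{key}: expected a number, got {value!r}")
        lo, hi = _SANITY.get(key, (None, None))
        if lo is not None and not (lo <= float(value) <= hi):
            raise ConfigError(
                f"{section}.{key}={value} is outside the plausible SI range "
                f"[{lo}, {hi}]; check units (all lengths in metres)"
            )
    try:
        params = cls(**{k: float(v) for k, v in data.items()})
    except ValueError as exc:
        raise ConfigError(f"section '{section}': {exc}") from exc
    if section == "membrane" and ({"V_chain", "c3_max"} & set(data)):
        params.warn_unused_fields()
    return params


def load_config(path: str | Path) -> tuple[MicroModelParams, MembraneModelParams]:
    """Load and validate a config file; absent keys fall back to the defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"micro", "membrane"}
    if unknown:
        raise ConfigError(
            f"{path}: unknown section(s) {sorted(unknown)}; "
            "expected 'micro' and/or 'membrane'"
        )
    micro = _build(MicroModelParams, "micro", raw.get("micro") or {})
    membrane = _build(MembraneModelParams, "membrane", raw.get("membrane") or {})
    return micro, membrane


def dump_config(micro: MicroModelParams, membrane: MembraneModelParams,
                path: str | Path | None = None) -> str:
    """Serialize both parameter sets to YAML; round-trips bit-exactly."""
    doc = {
        "micro": dataclasses.asdict(micro),
        "membrane": dataclasses.asdict(membrane),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
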