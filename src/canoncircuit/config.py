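"""Configuration files: one YAML/JSON document describing parameters,
network, stimulation protocol, measurement windows and simulation settings."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .analysis import MeasurementWindows
from .network import NetworkConfig, build_network
from .params import LOCATIONS, ModelParams, reference_params
from .protocol import GIPulse, Pulse, StimulusProtocol

__all__ = ["ResolvedConfig", "load_config", "resolved_dict", "save_config"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_TOP_KEYS = {"params", "network", "protocol", "windows", "sim"}


class ConfigError(ValueError):
    pass


@dataclass
class ResolvedConfig:
    params: ModelParams
    network: NetworkConfig
    protocol: StimulusProtocol
    windows: MeasurementWindows
    dt: float
    seed: int
    stride: int

    def to_dict(self) -> dict:
        return resolved_dict(self)


def _cell_from_label(net: NetworkConfig, label: str):
    try:
        return net.cells[net.index(label)]
    except (ValueError, IndexError):
        raise ConfigError(f"unknown cell {label!r} for this network") from None


def load_config(path) -> ResolvedConfig:
    """Parse and validate a config file; missing parameters default to the
    reference set.  Validation errors name the offending key."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key {sorted(unknown)[0]!r}")
    return resolve(doc)


def resolve(doc: dict) -> ResolvedConfig:
    pdoc = doc.get("params") or {}
    unknown = set(pdoc) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown key params.{sorted(unknown)[0]}")
    try:
        params = reference_params(**pdoc)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"params: {e}") from None

    ndoc = doc.get("network") or {}
    unknown = set(ndoc) - {"locations", "isolation"}
    if unknown:
        raise ConfigError(f"unknown key network.{sorted(unknown)[0]}")
    try:
        net = build_network(params, locations=int(ndoc.get("locations", 1)),
                            isolation=bool(ndoc.get("isolation", False)))
    except ValueError as e:
        raise ConfigError(f"network: {e}") from None

    prdoc = doc.get("protocol") or {}
    unknown = set(prdoc) - {"t_end", "pulses", "gi_pulses"}
    if unknown:
        raise ConfigError(f"unknown key protocol.{sorted(unknown)[0]}")
    pulses = []
    for i, p in enumerate(prdoc.get("pulses") or []):
        unknown = set(p) - {"target", "onset", "duration", "amplitude"}
        if unknown:
            raise ConfigError(f"unknown key protocol.pulses[{i}].{sorted(unknown)[0]}")
        try:
            pulses.append(Pulse(_cell_from_label(net, str(p["target"])),
                                float(p["onset"]), float(p["duration"]),
                                float(p.get("amplitude", params.I_exc_on))))
        except KeyError as e:
            raise ConfigError(f"protocol.pulses[{i}] missing key {e.args[0]!r}") from None
    gi = []
    for i, p in enumerate(prdoc.get("gi_pulses") or []):
        unknown = set(p) - {"onset", "duration", "strength"}
        if unknown:
            raise ConfigError(f"unknown key protocol.gi_pulses[{i}].{sorted(unknown)[0]}")
        gi.append(GIPulse(float(p["onset"]), float(p["duration"]), float(p["strength"])))
    try:
        protocol = StimulusProtocol(float(prdoc.get("t_end", 16.0)), tuple(pulses), tuple(gi))
    except ValueError as e:
        raise ConfigError(str(e)) from None

    wdoc = doc.get("windows") or {}
    unknown = set(wdoc) - {"baseline", "short_term", "long_term"}
    if unknown:
        raise ConfigError(f"unknown key windows.{sorted(unknown)[0]}")
    defaults = MeasurementWindows()
    try:
        windows = MeasurementWindows(
            tuple(wdoc.get("baseline", defaults.baseline)),
            tuple(wdoc.get("short_term", defaults.short_term)),
            tuple(wdoc.get("long_term", defaults.long_term)),
        )
    except ValueError as e:
        raise ConfigError(f"windows: {e}") from None

    sdoc = doc.get("sim") or {}
    unknown = set(sdoc) - {"dt", "seed", "stride"}
    if unknown:
        raise ConfigError(f"unknown key sim.{sorted(unknown)[0]}")
    dt = float(sdoc.get("dt", 5e-4))
    if dt <= 0:
        raise ConfigError("sim.dt must be positive")
    stride = int(sdoc.get("stride", 1))
    if stride < 1:
        raise ConfigError("sim.stride must be >= 1")
    return ResolvedConfig(params, net, protocol, windows, dt, int(sdoc.get("seed", 0)), stride)


def resolved_dict(cfg: ResolvedConfig) -> dict:
    """Fully-resolved config as a plain dict (round-trips through resolve)."""
    return {
        "params": cfg.params.to_dict(),
        "network": {
            "locations": len({c.location for c in cfg.network.cells}),
            "isolation": cfg.network.isolation,
        },
        "protocol": {
            "t_end": cfg.protocol.t_end,
            "pulses": [
                {"target": p.target.label, "onset": p.onset,
                 "duration": p.duration, "amplitude": p.amplitude}
                for p in cfg.protocol.pulses
            ],
            "gi_pulses": [
                {"onset": p.onset, "duration": p.duration, "strength": p.strength}
                for p in cfg.protocol.gi_pulses
            ],
        },
        "windows": {
            "baseline": list(cfg.windows.baseline),
            "short_term": list(cfg.windows.short_term),
            "long_term": list(cfg.windows.long_term),
        },
        "sim": {"dt": cfg.dt, "seed": cfg.seed, "stride": cfg.stride},
    }


def save_config(cfg: ResolvedConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(resolved_dict(cfg), fh, sort_keys=False)
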