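"""Named device and subject presets, loaded from the shipped config files."""

from __future__ import annotations

from importlib import resources

import yaml

from .subject import SubjectParams
from .timing import DeviceModel

__all__ = ["device_preset", "subject_preset", "device_preset_names",
           "subject_preset_names"]


def _load_yaml(filename: str) -> dict:
    with resources.files("pvtsim.data").joinpath(filename).open("r") as fh:
        return yaml.safe_load(fh)


def device_preset(name: str) -> DeviceModel:
    """A named device chain: ``reference`` (zero delay, the RT-box role),
    ``gaming`` (1000-Hz poll) or ``standard`` (125-Hz poll, extra latency)."""
    presets = _load_yaml("devices.yaml")
    if name not in presets:
        raise KeyError(f"unknown device preset {name!r}; "
                       f"available: {sorted(presets)}")
    return DeviceModel(name=name, **presets[name])


def subject_preset(name: str) -> SubjectParams:
    """A named synthetic subject: ``satiated`` or ``tsd85h``."""
    presets = _load_yaml("subjects.yaml")
    if name not in presets:
        raise KeyError(f"unknown subject preset {name!r}; "
                       f"available: {sorted(presets)}")
    return SubjectParams(name=name, **presets[name])


def device_preset_names() -> list[str]:
    return sorted(_load_yaml("devices.yaml"))


def subject_preset_names() -> list[str]:
    return sorted(_load_yaml("subjects.yaml"))
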