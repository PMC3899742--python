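"""Built-in parameter presets, shipped as YAML files.

``no_cta`` is the baseline calibration (untreated plateau ~45/115);
``with_cta`` is the elevated-baseline calibration (untreated plateau of
proliferating cells = 100) used for chemotherapy runs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from ..model import ModelParameters

__all__ = ["Preset", "load_preset", "available_presets"]


@dataclass(frozen=True)
class Preset:
    """A named parameter set with its initial conditions."""

    name: str
    params: ModelParameters
    P0: float
    N0: float


def available_presets() -> tuple[str, ...]:
    return ("no_cta", "with_cta")


def load_preset(name: str) -> Preset:
    if name not in available_presets():
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        )
    text = (
        importlib.resources.files(__package__)
        .joinpath(f"{name}.yaml")
        .read_text()
    )
    raw = yaml.safe_load(text)
    P0 = float(raw.pop("P0"))
    N0 = float(raw.pop("N0"))
    return Preset(name=name, params=ModelParameters(**raw), P0=P0, N0=N0)
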