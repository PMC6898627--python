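"""Shipped scenario presets.

Two presets reproduce the reference bench conditions for the anti-tubercular
drugs used to exercise the model: freely soluble moxifloxacin
(C_s = 17.70 mg/mL) and poorly soluble ethionamide (C_s = 0.46 mg/mL), each
as a 50 µg dose in 25 µL of mucus simulant over a 4.91 cm² dialysis membrane
(hydrated thickness 62.5 µm) perfused at 0.4 mL/min into a 500 µL receiver.
"""

from __future__ import annotations

from importlib import resources

from .exceptions import ConfigError
from .io import Preset, load_config

__all__ = ["PRESET_NAMES", "get_preset", "preset_path"]

PRESET_NAMES = ("moxifloxacin_table1", "ethionamide_table1")


def preset_path(name: str):
    """Filesystem path of a shipped preset YAML (context-manager-free access)."""
    if name not in PRESET_NAMES:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return resources.files("mucoperm").joinpath("presets", f"{name}.yaml")


def get_preset(name: str) -> Preset:
    """Load a shipped preset by name."""
    return load_config(preset_path(name))
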