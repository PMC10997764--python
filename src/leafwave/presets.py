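"""Frozen stress-archetype presets.

The four archetypes (wounding, Xcc infection, high light, high heat)
are stored as a plain-text YAML file packaged with the library.  Each
entry carries the kinetic rate constants and pools of the local
waveform, the H₂O₂ front speed, and the SA source-onset/diffusion pair;
the values are fixtures chosen once so the noise-free generator output
reproduces each archetype's characteristic wave features, and are not
re-derived at run time.

``preset_dict(label)`` returns the raw mapping; use
:func:`leafwave.synth.preset` for a ready :class:`~leafwave.synth.SynthConfig`,
or :func:`kinetic_preset` for the kinetics alone.  A user YAML file with
the same layout can be supplied instead of the packaged one.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["preset_dict", "kinetic_preset", "load_preset_file"]


@lru_cache(maxsize=None)
def _builtin() -> dict:
    text = resources.files("leafwave").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def load_preset_file(path: str | Path) -> dict:
    """Load a user preset file (same YAML layout as the packaged one)."""
    return yaml.safe_load(Path(path).read_text())


def preset_dict(label: str, source: dict | None = None) -> dict:
    table = source if source is not None else _builtin()
    if label not in table:
        raise ValueError(
            f"unknown preset '{label}'; available: {sorted(table)}"
        )
    return dict(table[label])


def kinetic_preset(label: str, source: dict | None = None):
    """The frozen :class:`~leafwave.kinetics.KineticParams` of one archetype."""
    from .kinetics import KineticParams

    d = preset_dict(label, source)
    if not d.get("kinetics"):
        raise ValueError(f"preset '{label}' has no kinetic parameters")
    return KineticParams.from_dict(d["kinetics"])
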