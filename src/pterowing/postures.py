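"""Loading of shipped and user posture presets."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import yaml

from .planform import PostureSpec


def _spec_from_entry(name: str, entry: dict) -> PostureSpec:
    return PostureSpec(
        name=name,
        sweep={k: float(v) for k, v in entry["sweep"].items()},
        femur_angle=float(entry.get("femur_angle", 45.0)),
        tibia_parallel=bool(entry.get("tibia_parallel", True)),
    )


def load_postures(path: str | Path | None = None) -> dict[str, PostureSpec]:
    """Posture presets from a YAML file (default: the shipped presets)."""
    if path is None:
        text = files("pterowing.data").joinpath("postures.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: _spec_from_entry(name, entry) for name, entry in raw.items()}


def get_posture(taxon: str, kind: str = "taxon_specific",
                path: str | Path | None = None) -> PostureSpec:
    """The pose used for a taxon: its own preset or the shared neutral pose."""
    presets = load_postures(path)
    if kind == "neutral":
        return presets["neutral"]
    if kind != "taxon_specific":
        raise ValueError(f"unknown posture kind {kind!r}")
    if taxon not in presets:
        raise KeyError(f"no posture preset for taxon {taxon!r}")
    return presets[taxon]
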