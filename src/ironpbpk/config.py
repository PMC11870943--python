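"""Loading of packaged physiology and parameter presets (YAML)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .model_core import KineticParameters, OrganSpec, SpeciesPhysiology

SPECIES = ("mouse", "rat", "human")
MOUSE_DIETS = ("iron_deficient", "iron_adequate", "iron_loaded")


def _read_packaged(name: str) -> dict:
    with resources.files("ironpbpk.presets").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def physiology_from_dict(d: Mapping) -> SpeciesPhysiology:
    organs = tuple(
        OrganSpec(name=o["name"], volume=float(o["volume"]), flow=float(o["flow"]),
                  drains_to=o.get("drains_to", ""))
        for o in d["organs"]
    )
    return SpeciesPhysiology(
        species=d["species"],
        body_weight=float(d["body_weight"]),
        cardiac_output=float(d["cardiac_output"]),
        plasma_volume=float(d["plasma_volume"]),
        organs=organs,
    )


def load_physiology(species: str) -> SpeciesPhysiology:
    """Load a packaged species physiology (mouse, rat, or human).

    The mouse values are the study physiology; rat and human presets are
    reconstructed from standard reference compilations (see the YAML headers).
    """
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")
    return physiology_from_dict(_read_packaged(f"physiology_{species}.yaml"))


def load_physiology_file(path: str | Path) -> SpeciesPhysiology:
    with open(path) as fh:
        return physiology_from_dict(yaml.safe_load(fh))


def list_parameter_presets() -> tuple[str, ...]:
    return tuple(_read_packaged("parameters.yaml"))


def load_parameters(preset: str) -> KineticParameters:
    """Load a named kinetic-parameter preset.

    Mouse presets are keyed ``mouse_iron_deficient`` / ``mouse_iron_adequate``
    / ``mouse_iron_loaded``; ``rat_ida`` holds the iron-deficient rat set.
    """
    table = _read_packaged("parameters.yaml")
    if preset not in table:
        raise KeyError(f"unknown parameter preset {preset!r}; "
                       f"available: {tuple(table)}")
    return KineticParameters.from_dict(table[preset])


def load_parameters_file(path: str | Path) -> KineticParameters:
    with open(path) as fh:
        return KineticParameters.from_dict(yaml.safe_load(fh))
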