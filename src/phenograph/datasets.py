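"""Loaders for the packaged example data.

The package ships a worked example: the seeded term vocabulary, the two
Malagasy dung-beetle descriptions in the DSL, the dichotomous key to adult
Malagasy *Scarabaeus*, and the specimen (occurrence) records for both
species, all as small plain-text files.
"""

from __future__ import annotations

from importlib import resources

from .dsl import SemanticDescription, parse_description
from .dwc import OccurrenceRecord, parse_records
from .key import Key, load_key
from .registry import TermRegistry

__all__ = [
    "data_text",
    "load_registry",
    "load_description",
    "load_malagasy_key",
    "load_materials",
]

SPECIES = ("sakalava", "viettei")


def data_text(name: str) -> str:
    return (resources.files("phenograph") / "data" / name).read_text(encoding="utf-8")


def load_registry() -> TermRegistry:
    """The seeded vocabulary covering both packaged descriptions."""
    return TermRegistry.from_yaml(data_text("vocabulary.yaml"))


def load_description(species: str, registry: TermRegistry | None = None) -> SemanticDescription:
    """Parse the packaged description for ``"sakalava"`` or ``"viettei"``."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    registry = registry or load_registry()
    return parse_description(data_text(f"{species}.phs"), registry)


def load_malagasy_key() -> Key:
    """The identification key to adult Malagasy Scarabaeus."""
    return load_key(data_text("malagasy_scarabaeus_key.yaml"))


def load_materials(species: str) -> list[OccurrenceRecord]:
    """The printed specimen records for one species."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    return parse_records(data_text(f"{species}_materials.txt"))
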