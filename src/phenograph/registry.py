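"""Controlled-vocabulary registry for prefixed ontology terms.

Descriptions reference anatomy, quality, relation and unit terms through
compact tokens such as ``aism-pronotum`` or ``ro-encircles``: a lowercase
namespace prefix, a hyphen, and a snake_case local name.  The registry
resolves those tokens, builds OBO-style IRIs from a prefix table, mints
consecutive numeric identifiers for newly created terms, and keeps an
explicit, symmetric record of homology statements (e.g. the tibial
cuticular spine being homologous to the tibial spur it replaces).

The vocabulary is persisted as a small YAML file; no ontology release is
ever fetched or parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import yaml

__all__ = [
    "OntologyTerm",
    "TermRegistry",
    "RegistryError",
    "MalformedTokenError",
    "UnknownPrefixError",
    "UnknownTermError",
    "MintingError",
    "UnregisteredTermError",
]

_NUMERIC_ID = re.compile(r"^\d{7}$")
_LOCAL_NAME = re.compile(r"^[a-z0-9][a-z0-9_]*$")


class RegistryError(ValueError):
    """Base class for registry failures."""


class MalformedTokenError(RegistryError):
    """A DSL token without a ``prefix-local_name`` shape."""


class UnknownPrefixError(RegistryError):
    def __init__(self, prefix: str):
        self.prefix = prefix
        super().__init__(f"unknown ontology prefix: {prefix!r}")


class UnknownTermError(RegistryError):
    def __init__(self, prefix: str, local_name: str):
        self.prefix = prefix
        self.local_name = local_name
        super().__init__(f"unknown term: {prefix.lower()}-{local_name}")


class MintingError(RegistryError):
    """Invalid identifier range or name list passed to :meth:`TermRegistry.mint_range`."""


class UnregisteredTermError(RegistryError):
    """A homology record may only link terms already in the registry."""


@dataclass(frozen=True)
class OntologyTerm:
    """One controlled-vocabulary entry.

    ``numeric_id`` is the zero-padded 7-digit accession (e.g. ``"0000527"``
    for the cuticular spine) when the term has one; purely local terms carry
    only a slug.  ``label`` is the exact human-readable form used by the
    natural-language renderer, so it may differ from the underscore form of
    ``local_name`` (hyphens, Roman numerals, ...).
    """

    prefix: str
    local_name: str
    label: str
    numeric_id: Optional[str] = None
    definition: Optional[str] = None
    is_relation: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise RegistryError(f"term {self.prefix}-{self.local_name} has an empty label")
        if self.numeric_id is not None and not _NUMERIC_ID.match(self.numeric_id):
            raise RegistryError(
                f"numeric_id must be exactly 7 decimal digits, got {self.numeric_id!r}"
            )
        if not _LOCAL_NAME.match(self.local_name):
            raise RegistryError(f"invalid local name: {self.local_name!r}")

    @property
    def token(self) -> str:
        """The DSL token form, e.g. ``aism-flagellomere_5``."""
        return f"{self.prefix.lower()}-{self.local_name}"

    @property
    def curie(self) -> Optional[str]:
        return f"{self.prefix}:{self.numeric_id}" if self.numeric_id else None


class TermRegistry:
    """Deterministic lookup table of :class:`OntologyTerm` entries.

    Terms are keyed by ``(PREFIX, local_name)``; prefixes are
    case-normalized to uppercase internally while DSL tokens use the
    lowercase form.  ``prefix_table`` maps each prefix to an IRI base used
    by the RDF compiler.
    """

    def __init__(self, prefix_table: Optional[dict[str, str]] = None):
        self.prefix_table: dict[str, str] = dict(prefix_table or {})
        self._terms: dict[tuple[str, str], OntologyTerm] = {}
        self._by_id: dict[tuple[str, str], OntologyTerm] = {}
        self._by_label: dict[str, list[OntologyTerm]] = {}
        self._homologies: list[frozenset[tuple[str, str]]] = []

    # -- population ---------------------------------------------------

    def add(self, term: OntologyTerm) -> OntologyTerm:
        prefix = term.prefix.upper()
        if prefix != term.prefix:
            term = OntologyTerm(
                prefix=prefix,
                local_name=term.local_name,
                label=term.label,
                numeric_id=term.numeric_id,
                definition=term.definition,
                is_relation=term.is_relation,
            )
        if prefix not in self.prefix_table:
            raise UnknownPrefixError(term.prefix)
        key = (prefix, term.local_name)
        if key in self._terms:
            raise RegistryError(f"duplicate term: {term.token}")
        if term.numeric_id is not None:
            idkey = (prefix, term.numeric_id)
            if idkey in self._by_id:
                raise RegistryError(f"duplicate identifier: {prefix}:{term.numeric_id}")
            self._by_id[idkey] = term
        self._terms[key] = term
        self._by_label.setdefault(term.label, []).append(term)
        return term

    def mint_range(
        self,
        prefix: str,
        first_id: str,
        last_id: str,
        names: Optional[Sequence[str]] = None,
        labels: Optional[Sequence[str]] = None,
    ) -> list[OntologyTerm]:
        """Mint consecutive zero-padded identifiers ``first_id..last_id``.

        When ``names`` is omitted the terms get placeholder local names of
        the form ``<prefix>_<id>`` (the accessions exist before any label is
        published for them).
        """
        prefix = prefix.upper()
        if prefix not in self.prefix_table:
            raise UnknownPrefixError(prefix)
        for value in (first_id, last_id):
            if not _NUMERIC_ID.match(value):
                raise MintingError(f"identifier must be 7 digits, got {value!r}")
        lo, hi = int(first_id), int(last_id)
        if lo > hi:
            raise MintingError(f"inverted identifier range: {first_id} > {last_id}")
        size = hi - lo + 1
        if names is not None and len(names) != size:
            raise MintingError(f"{size} identifiers but {len(names)} names supplied")
        if labels is not None and len(labels) != size:
            raise MintingError(f"{size} identifiers but {len(labels)} labels supplied")
        ids = [f"{i:07d}" for i in range(lo, hi + 1)]
        for numeric_id in ids:
            if (prefix, numeric_id) in self._by_id:
                raise MintingError(f"identifier already minted: {prefix}:{numeric_id}")
        minted = []
        for pos, numeric_id in enumerate(ids):
            local = names[pos] if names is not None else f"{prefix.lower()}_{numeric_id}"
            label = labels[pos] if labels is not None else f"{prefix}:{numeric_id}"
            minted.append(
                self.add(OntologyTerm(prefix, local, label=label, numeric_id=numeric_id))
            )
        return minted

    # -- lookup --------------------------------------------------------

    def resolve(self, token: str) -> OntologyTerm:
        """Resolve a ``prefix-local_name`` DSL token to its registered term."""
        prefix, sep, local = token.partition("-")
        if not sep or not prefix or not local:
            raise MalformedTokenError(f"malformed term token (expected prefix-name): {token!r}")
        prefix = prefix.upper()
        if prefix not in self.prefix_table:
            raise UnknownPrefixError(token.partition("-")[0])
        try:
            return self._terms[(prefix, local)]
        except KeyError:
            raise UnknownTermError(prefix, local) from None

    def get(self, prefix: str, local_name: str) -> OntologyTerm:
        return self.resolve(f"{prefix.lower()}-{local_name}")

    def find_by_label(self, label: str) -> OntologyTerm:
        hits = self._by_label.get(label, [])
        if not hits:
            raise UnknownTermError("?", label.replace(" ", "_"))
        if len(hits) > 1:
            raise RegistryError(f"ambiguous label {label!r}: " + ", ".join(t.token for t in hits))
        return hits[0]

    def __contains__(self, term: OntologyTerm) -> bool:
        return self._terms.get((term.prefix.upper(), term.local_name)) == term

    def __iter__(self) -> Iterator[OntologyTerm]:
        return iter(self._terms.values())

    def __len__(self) -> int:
        return len(self._terms)

    @property
    def relation_terms(self) -> list[OntologyTerm]:
        return [t for t in self._terms.values() if t.is_relation]

    def iri(self, term: OntologyTerm) -> str:
        """OBO-style IRI: prefix base + numeric id when present, else slug."""
        base = self.prefix_table[term.prefix.upper()]
        return base + (term.numeric_id if term.numeric_id else term.local_name)

    # -- homology records ----------------------------------------------

    def register_homology(self, a: OntologyTerm, b: OntologyTerm) -> frozenset:
        """Record that ``a`` and ``b`` are homologous (symmetric, idempotent)."""
        for term in (a, b):
            if term not in self:
                raise UnregisteredTermError(f"term not registered: {term.token}")
        record = frozenset({(a.prefix, a.local_name), (b.prefix, b.local_name)})
        if record not in self._homologies:
            self._homologies.append(record)
        return record

    def homologous(self, a: OntologyTerm, b: OntologyTerm) -> bool:
        record = frozenset({(a.prefix, a.local_name), (b.prefix, b.local_name)})
        return record in self._homologies

    @property
    def homologies(self) -> list[frozenset]:
        return list(self._homologies)

    # -- persistence ---------------------------------------------------

    @classmethod
    def from_yaml(cls, source: str | Path) -> "TermRegistry":
        if isinstance(source, Path) or "\n" not in str(source):
            data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        else:
            data = yaml.safe_load(source)
        registry = cls(prefix_table=data.get("prefixes", {}))
        for entry in data.get("terms", []):
            prefix, _, local = entry["token"].partition("-")
            registry.add(
                OntologyTerm(
                    prefix=prefix.upper(),
                    local_name=local,
                    label=entry.get("label", local.replace("_", " ")),
                    numeric_id=entry.get("id"),
                    definition=entry.get("definition"),
                    is_relation=bool(entry.get("relation", False)),
                )
            )
        for pair in data.get("homologies", []):
            a, b = (registry.resolve(tok) for tok in pair)
            registry.register_homology(a, b)
        return registry

    def to_yaml(self) -> str:
        terms = []
        for term in self._terms.values():
            entry: dict = {"token": term.token}
            if term.label != term.local_name.replace("_", " "):
                entry["label"] = term.label
            if term.numeric_id:
                entry["id"] = term.numeric_id
            if term.definition:
                entry["definition"] = term.definition
            if term.is_relation:
                entry["relation"] = True
            terms.append(entry)
        data = {"prefixes": dict(self.prefix_table), "terms": terms}
        if self._homologies:
            data["homologies"] = [
                sorted(f"{p.lower()}-{l}" for p, l in record) for record in self._homologies
            ]
        return yaml.safe_dump(data, sort_keys=False, allow_unicode=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")
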