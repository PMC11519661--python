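"""Deterministic natural-language rendering of semantic descriptions.

Each statement becomes exactly one clause in the style of published
semantic treatments: path terms joined by ``", "``, the quality after
``": "``, relations and comparators spelled out with spaces, and a ``";"``
terminator — e.g. ``male organism, pronotum, dorsal region: convex;``.
Object and reference paths are written leaf-first with ``of`` ("postero-
lateral margin of abdominal sternite VIII"), mirroring the printed style.

Rendering is a pure function of the description: no aggregation, no
pronouns, no state.  Because the clause grammar is closed, the rendered
markdown is itself machine-readable; :func:`parse_rendered` recovers the
exact statement list, which gives the parse -> render -> parse fixpoint.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass

from .dsl import (
    ComparativeStatement,
    EntityPath,
    MeasurementStatement,
    MetadataStatement,
    QualityStatement,
    RelationalStatement,
    SemanticDescription,
    Statement,
)
from .registry import TermRegistry

__all__ = [
    "RenderedDescription",
    "render",
    "render_statement",
    "parse_rendered",
    "UnsupportedFormatError",
    "ClauseParseError",
]

METADATA_LABELS = {
    "catalog_number": "Catalog Number",
    "has_role_in_modeling": "has role in modeling",
    "denotes": "denotes",
    "parent_name_usage_id": "Parent Name Usage ID",
    "taxon_id": "Taxon ID",
}
_LABELS_TO_KEYS = {v: k for k, v in METADATA_LABELS.items()}


class UnsupportedFormatError(ValueError):
    pass


class ClauseParseError(ValueError):
    pass


def _words(token: str) -> str:
    return token.replace("_", " ")


def _subject_text(path: EntityPath) -> str:
    return ", ".join(step.label for step in path.steps)


def _of_chain(path: EntityPath) -> str:
    """Leaf-first 'of' chain used for relation objects and comparison references."""
    return " of ".join(step.label for step in reversed(path.steps))


def render_statement(stmt: Statement) -> str:
    """Render one statement as its clause text (terminated by ``;``)."""
    if isinstance(stmt, QualityStatement):
        return f"{_subject_text(stmt.subject)}: {stmt.quality.label};"
    if isinstance(stmt, RelationalStatement):
        clause = f"{_subject_text(stmt.subject)} {_words(stmt.relation.local_name)} {_of_chain(stmt.object)}"
        if stmt.attached_quality is not None:
            clause += f": {stmt.attached_quality.label}"
        return clause + ";"
    if isinstance(stmt, ComparativeStatement):
        return (
            f"{_subject_text(stmt.subject)}: {stmt.attribute} {_words(stmt.comparator)} "
            f"{stmt.reference_attribute} of {_of_chain(stmt.reference)};"
        )
    if isinstance(stmt, MeasurementStatement):
        return (
            f"{_subject_text(stmt.subject)}, {stmt.attribute} = {repr(stmt.value)}, "
            f"unit: {stmt.unit.label};"
        )
    raise TypeError(f"not a renderable statement: {stmt!r}")


@dataclass(frozen=True)
class RenderedDescription:
    clauses: tuple[str, ...]
    format: str
    header: tuple[str, ...] = ()
    sections: tuple[tuple[str, str], ...] = ()
    taxon_label: str = ""

    @property
    def text(self) -> str:
        if self.format == "markdown":
            parts: list[str] = []
            if self.taxon_label:
                parts.append(f"# {self.taxon_label}\n")
            if self.header:
                parts.append("\n".join(self.header) + "\n")
            parts.append("\n".join(self.clauses))
            for title, body in self.sections:
                parts.append(f"\n## {title}\n\n{body}")
            return "\n".join(parts) + "\n"
        if self.format == "html":
            parts = ["<article>"]
            if self.taxon_label:
                parts.append(f"<h1>{_html.escape(self.taxon_label)}</h1>")
            if self.header:
                parts.append("<ul class=\"metadata\">")
                parts.extend(f"<li>{_html.escape(line)}</li>" for line in self.header)
                parts.append("</ul>")
            parts.append("<ul class=\"description\">")
            parts.extend(f"<li>{_html.escape(clause)}</li>" for clause in self.clauses)
            parts.append("</ul>")
            for title, body in self.sections:
                parts.append(f"<h2>{_html.escape(title)}</h2>")
                parts.append(f"<p>{_html.escape(body)}</p>")
            parts.append("</article>")
            return "\n".join(parts) + "\n"
        raise UnsupportedFormatError(self.format)


def _section_title(key: str) -> str:
    return key.replace("_", " ").capitalize()


def render(desc: SemanticDescription, format: str = "markdown") -> RenderedDescription:
    """Render a description; clause i corresponds to statement i."""
    if format not in ("markdown", "html"):
        raise UnsupportedFormatError(format)
    header = tuple(
        f"{METADATA_LABELS[m.key]}: {m.value};" for m in desc.metadata
    )
    clauses = tuple(render_statement(s) for s in desc.statements)
    sections = tuple((_section_title(k), v) for k, v in desc.annotations.items())
    return RenderedDescription(
        clauses=clauses,
        format=format,
        header=header,
        sections=sections,
        taxon_label=desc.taxon_label,
    )


# ---------------------------------------------------------------------------
# inverse: parse rendered markdown back into statements

_MEASUREMENT_RE = re.compile(
    r"^(?P<subject>.+), (?P<attr>width|length|amount) = (?P<value>\d+(?:\.\d+)?), "
    r"unit: (?P<unit>.+)$"
)
_COMPARATIVE_RE = re.compile(
    r"^(?P<subject>.+): (?P<attr>width|length|amount) "
    r"(?P<comparator>larger than|similar in magnitude relative to) "
    r"(?P<refattr>width|length|amount) of (?P<reference>.+)$"
)


def _resolve_path(text: str, registry: TermRegistry) -> EntityPath:
    labels = [part.strip() for part in text.split(", ")]
    return EntityPath(tuple(registry.find_by_label(label) for label in labels))


def _resolve_of_chain(text: str, registry: TermRegistry) -> EntityPath:
    labels = [part.strip() for part in text.split(" of ")]
    return EntityPath(tuple(registry.find_by_label(label) for label in reversed(labels)))


def _parse_clause(clause: str, registry: TermRegistry) -> Statement:
    body = clause.strip().rstrip(";")
    match = _MEASUREMENT_RE.match(body)
    if match:
        return MeasurementStatement(
            _resolve_path(match.group("subject"), registry),
            match.group("attr"),
            float(match.group("value")),
            registry.find_by_label(match.group("unit")),
        )
    match = _COMPARATIVE_RE.match(body)
    if match:
        return ComparativeStatement(
            _resolve_path(match.group("subject"), registry),
            match.group("attr"),
            match.group("comparator").replace(" ", "_"),
            match.group("refattr"),
            _resolve_of_chain(match.group("reference"), registry),
        )
    relation_names = sorted(
        (t.local_name for t in registry.relation_terms), key=len, reverse=True
    )
    if relation_names:
        rel_re = "|".join(re.escape(_words(name)) for name in relation_names)
        match = re.match(rf"^(?P<subject>.+?) (?P<rel>{rel_re}) (?P<rest>.+)$", body)
        if match:
            relation = next(
                t
                for t in registry.relation_terms
                if _words(t.local_name) == match.group("rel")
            )
            rest = match.group("rest")
            attached = None
            if ": " in rest:
                rest, _, quality_label = rest.rpartition(": ")
                attached = registry.find_by_label(quality_label.strip())
            return RelationalStatement(
                _resolve_path(match.group("subject"), registry),
                relation,
                _resolve_of_chain(rest, registry),
                attached,
            )
    if ": " not in body:
        raise ClauseParseError(f"cannot parse clause: {clause!r}")
    subject_text, _, quality_label = body.rpartition(": ")
    return QualityStatement(
        _resolve_path(subject_text, registry), registry.find_by_label(quality_label.strip())
    )


def parse_rendered(text: str, registry: TermRegistry) -> SemanticDescription:
    """Parse rendered markdown back into a :class:`SemanticDescription`."""
    taxon_label = ""
    metadata: list[MetadataStatement] = []
    statements: list[Statement] = []
    annotations: dict[str, str] = {}
    section_key: str | None = None
    section_body: list[str] = []

    def flush_section() -> None:
        nonlocal section_key, section_body
        if section_key is not None:
            annotations[section_key] = "\n".join(section_body).strip()
        section_key, section_body = None, []

    for raw in text.split("\n"):
        line = raw.rstrip()
        if line.startswith("## "):
            flush_section()
            section_key = line[3:].strip().lower().replace(" ", "_")
            continue
        if section_key is not None:
            section_body.append(line)
            continue
        if not line.strip():
            continue
        if line.startswith("# "):
            taxon_label = line[2:].strip()
            continue
        stripped = line.strip()
        prefix = stripped.split(": ", 1)[0]
        if prefix in _LABELS_TO_KEYS:
            value = stripped.split(": ", 1)[1].rstrip(";")
            metadata.append(MetadataStatement(_LABELS_TO_KEYS[prefix], value))
            continue
        statements.append(_parse_clause(stripped, registry))
    flush_section()
    return SemanticDescription(
        taxon_label=taxon_label,
        statements=statements,
        metadata=metadata,
        annotations=annotations,
        registry=registry,
    )
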