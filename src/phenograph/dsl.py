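"""Phenotype-description DSL: statement model and parser.

A description file is a UTF-8 text in a compact entity--quality dialect:

* ``#`` starts a comment running to end of line;
* ``@key value`` directives before the first statement carry description
  metadata (``@taxon``, ``@catalog_number``, ``@taxon_id``, ...), and
  ``@annotation <key>`` ... ``@end`` blocks hold opaque free-text sections
  (sexual dimorphism, variation);
* one statement per ``;``, built from prefixed ontology tokens:

  ==============================  =============================================
  quality                         ``aism-pronotum > aism-dorsal_region: pato-convex;``
  relation                        ``aism-insect_leg .ro-encircles aism-cuticular_seta: pato-red_brown;``
  comparison                      ``aism-pronotum: width larger_than length of aism-pronotum;``
  measurement                     ``aism-male_organism: length = 23.0, unit: uo-millimeter;``
  grouping                        ``colao-antennal_club > (aism-flagellomere_5, aism-flagellomere_6): pato-present;``
  block scoping                   ``aism-pronotum { aism-dorsal_region: pato-convex; }``
  ==============================  =============================================

Entity paths chain terms with ``>`` where each step is, by default, a part
of its parent.  A parenthesised group names several sibling parts at once;
the parser expands a grouped statement into one statement per leaf, so the
in-memory statement stream is always flat and ordered exactly as authored.
Block scoping prefixes every inner subject path with the block path, which
mirrors the shared-context style of printed description blocks.

Comparisons use a closed comparator set (``larger_than``,
``similar_in_magnitude_relative_to``) over the closed magnitude-attribute
set (``width``, ``length``, ``amount``); anything else is a syntax error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .registry import OntologyTerm, RegistryError, TermRegistry

__all__ = [
    "COMPARATORS",
    "MAGNITUDE_ATTRIBUTES",
    "METADATA_KEYS",
    "EntityPath",
    "QualityStatement",
    "RelationalStatement",
    "ComparativeStatement",
    "MeasurementStatement",
    "MetadataStatement",
    "Statement",
    "SemanticDescription",
    "Issue",
    "PhenoscriptSyntaxError",
    "TermResolutionError",
    "parse_description",
    "parse_entity_path",
    "canonical_path",
    "canonical_leaf_paths",
    "extract_measurements",
    "validate",
    "to_source",
]

COMPARATORS = ("larger_than", "similar_in_magnitude_relative_to")
MAGNITUDE_ATTRIBUTES = ("width", "length", "amount")
METADATA_KEYS = (
    "catalog_number",
    "has_role_in_modeling",
    "denotes",
    "taxon_id",
    "parent_name_usage_id",
)


class PhenoscriptSyntaxError(ValueError):
    def __init__(self, message: str, line: int, column: int = 0):
        self.line = line
        self.column = column
        super().__init__(f"line {line}: {message}")


class TermResolutionError(ValueError):
    """One or more tokens did not resolve; carries (line, token, reason) triples."""

    def __init__(self, failures: list[tuple[int, str, str]]):
        self.failures = failures
        lines = "; ".join(f"line {ln}: {tok} ({why})" for ln, tok, why in failures)
        super().__init__(f"unresolvable terms: {lines}")


# ---------------------------------------------------------------------------
# entity paths


@dataclass(frozen=True)
class EntityPath:
    """An anatomical location: a part-of chain from organism to part.

    ``steps`` holds single terms; an optional trailing ``group`` names
    several sibling leaves sharing the same parent chain (the antennal-club
    flagellomere idiom).
    """

    steps: tuple[OntologyTerm, ...]
    group: tuple[OntologyTerm, ...] = ()

    def __post_init__(self) -> None:
        if not self.steps and not self.group:
            raise ValueError("empty entity path")
        if len(self.group) == 1:
            raise ValueError("a grouping step needs at least two members")

    @property
    def is_grouped(self) -> bool:
        return bool(self.group)

    @property
    def leaf(self) -> OntologyTerm:
        if self.is_grouped:
            raise ValueError("grouped path has no single leaf")
        return self.steps[-1]

    def expand(self) -> tuple["EntityPath", ...]:
        """One ungrouped path per leaf (identity for ungrouped paths)."""
        if not self.is_grouped:
            return (self,)
        return tuple(EntityPath(self.steps + (member,)) for member in self.group)

    def prefixes(self) -> tuple["EntityPath", ...]:
        """Every ancestor path, shortest first, including the path itself."""
        out = [EntityPath(self.steps[: i + 1]) for i in range(len(self.steps))]
        if self.is_grouped:
            out.extend(self.expand())
        return tuple(out)

    def child(self, term: OntologyTerm) -> "EntityPath":
        return EntityPath(self.steps + (term,))


def canonical_path(path: EntityPath) -> str:
    """Deterministic text key for an ungrouped path: labels joined by `` / ``."""
    if path.is_grouped:
        raise ValueError("grouped path maps to several keys; use canonical_leaf_paths")
    return " / ".join(step.label for step in path.steps)


def canonical_leaf_paths(path: EntityPath) -> tuple[str, ...]:
    """One canonical key per leaf (a single key for ungrouped paths)."""
    return tuple(canonical_path(p) for p in path.expand())


# ---------------------------------------------------------------------------
# statements


@dataclass(frozen=True)
class QualityStatement:
    subject: EntityPath
    quality: OntologyTerm


@dataclass(frozen=True)
class RelationalStatement:
    subject: EntityPath
    relation: OntologyTerm
    object: EntityPath
    attached_quality: Optional[OntologyTerm] = None


@dataclass(frozen=True)
class ComparativeStatement:
    subject: EntityPath
    attribute: str
    comparator: str
    reference_attribute: str
    reference: EntityPath


@dataclass(frozen=True)
class MeasurementStatement:
    subject: EntityPath
    attribute: str
    value: float
    unit: OntologyTerm

    def __post_init__(self) -> None:
        if not (self.value > 0 and self.value == self.value and self.value != float("inf")):
            raise ValueError(f"measurement value must be finite and > 0, got {self.value}")


@dataclass(frozen=True)
class MetadataStatement:
    key: str
    value: str

    def __post_init__(self) -> None:
        if self.key not in METADATA_KEYS:
            raise ValueError(f"unknown metadata key: {self.key!r}")


Statement = Union[
    QualityStatement, RelationalStatement, ComparativeStatement, MeasurementStatement
]


@dataclass
class SemanticDescription:
    """Ordered phenotype statements about one organism, plus header metadata
    and opaque free-text annotation sections."""

    taxon_label: str = ""
    statements: list = field(default_factory=list)
    metadata: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    registry: Optional[TermRegistry] = field(default=None, compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.statements)


@dataclass(frozen=True)
class Issue:
    code: str
    message: str
    line: Optional[int] = None


# ---------------------------------------------------------------------------
# tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<number>\d+\.\d+|\d+)
  | (?P<rel>\.[A-Za-z][A-Za-z0-9]*-[a-z0-9_]+)
  | (?P<term>[A-Za-z][A-Za-z0-9]*-[a-z0-9_]+)
  | (?P<word>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<sym>[><(){},:;=])
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Tok:
    kind: str
    value: str
    line: int
    column: int


def _tokenize(text: str, first_line: int = 1) -> list[_Tok]:
    tokens = []
    line, col = first_line, 1
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise PhenoscriptSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = match.lastgroup
        value = match.group()
        if kind not in ("ws", "comment"):
            tokens.append(_Tok(kind, value, line, col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = match.end()
    return tokens


# ---------------------------------------------------------------------------
# parser


class _Parser:
    def __init__(self, tokens: list[_Tok], registry: TermRegistry):
        self.tokens = tokens
        self.registry = registry
        self.pos = 0
        self.failures: list[tuple[int, str, str]] = []

    # token plumbing ---------------------------------------------------

    def peek(self, offset: int = 0) -> Optional[_Tok]:
        i = self.pos + offset
        return self.tokens[i] if i < len(self.tokens) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else _Tok("sym", "", 1, 1)
            raise PhenoscriptSyntaxError("unexpected end of input", last.line, last.column)
        self.pos += 1
        return tok

    def expect(self, value: str) -> _Tok:
        tok = self.next()
        if tok.value != value:
            raise PhenoscriptSyntaxError(
                f"expected {value!r}, found {tok.value!r}", tok.line, tok.column
            )
        return tok

    # term resolution --------------------------------------------------
    # unresolved tokens become a placeholder so parsing can continue and
    # every failure is reported at once; the error is raised before the
    # description is returned, so placeholders never escape

    _PLACEHOLDER = OntologyTerm("X", "unresolved", label="<unresolved>")

    def resolve(self, tok: _Tok) -> OntologyTerm:
        token = tok.value.lstrip(".")
        try:
            return self.registry.resolve(token)
        except RegistryError as exc:
            self.failures.append((tok.line, token, str(exc)))
            return self._PLACEHOLDER

    # grammar ----------------------------------------------------------

    def parse_path(self, context: tuple[OntologyTerm, ...] = ()) -> EntityPath:
        steps = list(context)
        group: tuple[OntologyTerm, ...] = ()
        while True:
            tok = self.peek()
            if tok is not None and tok.value == "(":
                self.next()
                members = [self.parse_term()]
                while self.peek() is not None and self.peek().value == ",":
                    self.next()
                    members.append(self.parse_term())
                self.expect(")")
                if len(members) >= 2:
                    group = tuple(members)
                else:  # single-member "group" degrades to a plain step
                    steps.extend(members)
                break
            steps.append(self.parse_term())
            nxt = self.peek()
            if nxt is not None and nxt.value == ">":
                self.next()
                continue
            break
        if not steps and not group:
            tok = self.peek() or _Tok("sym", "", 1, 1)
            raise PhenoscriptSyntaxError("expected an entity path", tok.line, tok.column)
        return EntityPath(tuple(steps), group)

    def parse_term(self) -> Optional[OntologyTerm]:
        tok = self.next()
        if tok.kind != "term":
            raise PhenoscriptSyntaxError(
                f"expected a prefixed ontology token, found {tok.value!r}",
                tok.line,
                tok.column,
            )
        return self.resolve(tok)

    def parse_statements(
        self, context: tuple[OntologyTerm, ...], out: list, stop_at_brace: bool
    ) -> None:
        while True:
            tok = self.peek()
            if tok is None:
                if stop_at_brace:
                    raise PhenoscriptSyntaxError("unclosed '{' block", 0, 0)
                return
            if tok.value == "}":
                if not stop_at_brace:
                    raise PhenoscriptSyntaxError("unmatched '}'", tok.line, tok.column)
                self.next()
                return
            self.parse_statement(context, out)

    def parse_statement(self, context: tuple[OntologyTerm, ...], out: list) -> None:
        subject = self.parse_path(context)
        tok = self.peek()
        if tok is None:
            raise PhenoscriptSyntaxError("unterminated statement", 0, 0)
        if tok.value == "{":
            if subject.is_grouped:
                raise PhenoscriptSyntaxError(
                    "a grouped path cannot open a block", tok.line, tok.column
                )
            self.next()
            self.parse_statements(subject.steps, out, stop_at_brace=True)
            return
        if tok.kind == "rel":
            self.next()
            relation = self.resolve(tok)
            obj = self.parse_path()
            attached = None
            if self.peek() is not None and self.peek().value == ":":
                self.next()
                attached = self.parse_term()
            self.expect(";")
            for sub in subject.expand():
                out.append(RelationalStatement(sub, relation, obj, attached))
            return
        if tok.value != ":":
            raise PhenoscriptSyntaxError(
                f"expected ':', a relation or a block, found {tok.value!r}",
                tok.line,
                tok.column,
            )
        self.next()
        nxt = self.peek()
        if nxt is not None and nxt.kind == "word":
            if nxt.value not in MAGNITUDE_ATTRIBUTES:
                raise PhenoscriptSyntaxError(
                    f"unknown magnitude attribute {nxt.value!r}", nxt.line, nxt.column
                )
            self.next()
            attribute = nxt.value
            after = self.next()
            if after.value == "=":
                value_tok = self.next()
                if value_tok.kind != "number":
                    raise PhenoscriptSyntaxError(
                        f"expected a number, found {value_tok.value!r}",
                        value_tok.line,
                        value_tok.column,
                    )
                self.expect(",")
                unit_kw = self.next()
                if unit_kw.value != "unit":
                    raise PhenoscriptSyntaxError(
                        f"expected 'unit', found {unit_kw.value!r}", unit_kw.line, unit_kw.column
                    )
                self.expect(":")
                unit = self.parse_term()
                self.expect(";")
                for sub in subject.expand():
                    out.append(
                        MeasurementStatement(sub, attribute, float(value_tok.value), unit)
                    )
                return
            if after.kind == "word":
                if after.value not in COMPARATORS:
                    raise PhenoscriptSyntaxError(
                        f"unknown comparator {after.value!r}", after.line, after.column
                    )
                ref_attr = self.next()
                if ref_attr.kind != "word" or ref_attr.value not in MAGNITUDE_ATTRIBUTES:
                    raise PhenoscriptSyntaxError(
                        f"expected a magnitude attribute, found {ref_attr.value!r}",
                        ref_attr.line,
                        ref_attr.column,
                    )
                of_kw = self.next()
                if of_kw.value != "of":
                    raise PhenoscriptSyntaxError(
                        f"expected 'of', found {of_kw.value!r}", of_kw.line, of_kw.column
                    )
                reference = self.parse_path()
                self.expect(";")
                for sub in subject.expand():
                    out.append(
                        ComparativeStatement(sub, attribute, after.value, ref_attr.value, reference)
                    )
                return
            raise PhenoscriptSyntaxError(
                f"expected '=' or a comparator after {attribute!r}", after.line, after.column
            )
        quality = self.parse_term()
        self.expect(";")
        for sub in subject.expand():
            out.append(QualityStatement(sub, quality))


# ---------------------------------------------------------------------------
# directives (metadata / annotations) are line-oriented and stripped before
# tokenizing the statement stream

_DIRECTIVE_RE = re.compile(r"^@(?P<key>[a-z_]+)\s*(?P<value>.*)$")


def _split_directives(source: str):
    statement_lines: list[tuple[int, str]] = []
    metadata: list[MetadataStatement] = []
    taxon_label = ""
    annotations: dict[str, str] = {}
    seen_keys: set[str] = set()
    lines = source.split("\n")
    i = 0
    while i < len(lines):
        raw = lines[i]
        stripped = raw.strip()
        if stripped.startswith("@"):
            match = _DIRECTIVE_RE.match(stripped)
            if not match:
                raise PhenoscriptSyntaxError(f"malformed directive: {stripped!r}", i + 1)
            key, value = match.group("key"), match.group("value").strip()
            if key == "taxon":
                taxon_label = value
            elif key == "annotation":
                body: list[str] = []
                i += 1
                while i < len(lines) and lines[i].strip() != "@end":
                    body.append(lines[i])
                    i += 1
                if i >= len(lines):
                    raise PhenoscriptSyntaxError("unterminated @annotation block", i)
                annotations[value] = "\n".join(body).strip()
            elif key in METADATA_KEYS:
                if key in seen_keys:
                    raise PhenoscriptSyntaxError(f"duplicate metadata key {key!r}", i + 1)
                seen_keys.add(key)
                metadata.append(MetadataStatement(key, value))
            else:
                raise PhenoscriptSyntaxError(f"unknown directive @{key}", i + 1)
        else:
            statement_lines.append((i + 1, raw))
        i += 1
    return taxon_label, metadata, annotations, statement_lines


def parse_description(source: str, registry: TermRegistry) -> SemanticDescription:
    """Parse DSL text into a :class:`SemanticDescription`.

    Grouped statements are expanded leaf-by-leaf and block scopes are
    resolved to fully qualified paths, so ``statements`` is flat and in
    authored order.  All unresolvable terms are collected and raised
    together as :class:`TermResolutionError` with their line numbers.
    """
    taxon_label, metadata, annotations, statement_lines = _split_directives(source)
    tokens: list[_Tok] = []
    for line_no, text in statement_lines:
        tokens.extend(_tokenize(text, first_line=line_no))
    parser = _Parser(tokens, registry)
    statements: list = []
    parser.parse_statements((), statements, stop_at_brace=False)
    if parser.failures:
        raise TermResolutionError(parser.failures)
    return SemanticDescription(
        taxon_label=taxon_label,
        statements=statements,
        metadata=metadata,
        annotations=annotations,
        registry=registry,
    )


def parse_entity_path(source: str, registry: TermRegistry) -> EntityPath:
    """Parse a bare entity-path fragment (supports ``>`` chains and grouping)."""
    parser = _Parser(_tokenize(source), registry)
    path = parser.parse_path()
    if parser.failures:
        raise TermResolutionError(parser.failures)
    if parser.peek() is not None:
        tok = parser.peek()
        raise PhenoscriptSyntaxError(f"trailing input {tok.value!r}", tok.line, tok.column)
    return path


# ---------------------------------------------------------------------------
# description-level operations


def extract_measurements(desc: SemanticDescription) -> list[tuple[str, str, float, str]]:
    """All measurements as ``(canonical path, attribute, value, unit label)``, in order."""
    return [
        (canonical_path(s.subject), s.attribute, s.value, s.unit.label)
        for s in desc.statements
        if isinstance(s, MeasurementStatement)
    ]


def validate(desc: SemanticDescription, registry: TermRegistry) -> list[Issue]:
    """Structural checks; returns issues instead of raising."""
    issues: list[Issue] = []

    def check_term(term: OntologyTerm, where: str) -> None:
        if term not in registry:
            issues.append(Issue("unresolved-term", f"{where}: {term.token} not in registry"))

    def check_path(path: EntityPath, where: str) -> None:
        for step in path.steps + path.group:
            check_term(step, where)

    for idx, stmt in enumerate(desc.statements):
        where = f"statement {idx + 1}"
        if isinstance(stmt, QualityStatement):
            check_path(stmt.subject, where)
            check_term(stmt.quality, where)
            if stmt.quality.is_relation:
                issues.append(
                    Issue("relation-as-quality", f"{where}: {stmt.quality.token} is a relation")
                )
        elif isinstance(stmt, RelationalStatement):
            check_path(stmt.subject, where)
            check_path(stmt.object, where)
            check_term(stmt.relation, where)
            if not stmt.relation.is_relation:
                issues.append(
                    Issue("not-a-relation", f"{where}: {stmt.relation.token} is not a relation")
                )
            if stmt.attached_quality is not None:
                check_term(stmt.attached_quality, where)
        elif isinstance(stmt, ComparativeStatement):
            check_path(stmt.subject, where)
            check_path(stmt.reference, where)
            if stmt.comparator not in COMPARATORS:
                issues.append(Issue("unknown-comparator", f"{where}: {stmt.comparator!r}"))
            for attr in (stmt.attribute, stmt.reference_attribute):
                if attr not in MAGNITUDE_ATTRIBUTES:
                    issues.append(Issue("unknown-attribute", f"{where}: {attr!r}"))
        elif isinstance(stmt, MeasurementStatement):
            check_path(stmt.subject, where)
            check_term(stmt.unit, where)
    seen: set[str] = set()
    for meta in desc.metadata:
        if meta.key in seen:
            issues.append(Issue("duplicate-metadata-key", f"metadata key {meta.key!r} repeated"))
        seen.add(meta.key)
    return issues


# ---------------------------------------------------------------------------
# canonical token-form serialization (flat dialect)


def _path_source(path: EntityPath) -> str:
    body = " > ".join(t.token for t in path.steps)
    if path.is_grouped:
        grouped = ", ".join(t.token for t in path.group)
        body = f"{body} > ({grouped})" if body else f"({grouped})"
    return body


def to_source(desc: SemanticDescription) -> str:
    """Serialize back to the flat token dialect (one statement per line)."""
    lines: list[str] = []
    if desc.taxon_label:
        lines.append(f"@taxon {desc.taxon_label}")
    for meta in desc.metadata:
        lines.append(f"@{meta.key} {meta.value}")
    for key, text in desc.annotations.items():
        lines.append(f"@annotation {key}")
        lines.append(text)
        lines.append("@end")
    if lines:
        lines.append("")
    for stmt in desc.statements:
        if isinstance(stmt, QualityStatement):
            lines.append(f"{_path_source(stmt.subject)}: {stmt.quality.token};")
        elif isinstance(stmt, RelationalStatement):
            clause = f"{_path_source(stmt.subject)} .{stmt.relation.token} {_path_source(stmt.object)}"
            if stmt.attached_quality is not None:
                clause += f": {stmt.attached_quality.token}"
            lines.append(clause + ";")
        elif isinstance(stmt, ComparativeStatement):
            lines.append(
                f"{_path_source(stmt.subject)}: {stmt.attribute} {stmt.comparator} "
                f"{stmt.reference_attribute} of {_path_source(stmt.reference)};"
            )
        elif isinstance(stmt, MeasurementStatement):
            lines.append(
                f"{_path_source(stmt.subject)}: {stmt.attribute} = {stmt.value}, "
                f"unit: {stmt.unit.token};"
            )
    return "\n".join(lines) + "\n"
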