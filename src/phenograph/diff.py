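"""Statement-level comparison of two semantic descriptions.

Statements are matched on a conservative key — canonical subject path +
statement kind + magnitude attribute (and relation name for relational
statements) — and compared term-wise.  Shared subjects whose value terms
differ (a quality swapped for another, an orientation, an angle) land in
``changed``; statements whose subject path exists in only one description
(structural differences such as an extra region level) land in
``only_in_a`` / ``only_in_b``; measurements are compared numerically into
``measurement_deltas``.  Header metadata is diffed separately into
``metadata_changes``.

Within one key, duplicate statements are compared positionally after
identical pairs have been cancelled, so statement order never affects
which differences are found — only how leftovers are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dsl import (
    ComparativeStatement,
    MeasurementStatement,
    QualityStatement,
    RelationalStatement,
    SemanticDescription,
    Statement,
    canonical_path,
)
from .nl import render_statement

__all__ = ["DiffReport", "ChangedEntry", "diff", "summarize_diagnosis", "RegistryMismatchError"]


class RegistryMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class ChangedEntry:
    path: str
    kind: str
    attribute: Optional[str]
    value_a: str
    value_b: str
    statement_a: Optional[Statement] = field(default=None, compare=False, repr=False)
    statement_b: Optional[Statement] = field(default=None, compare=False, repr=False)


@dataclass
class DiffReport:
    only_in_a: list = field(default_factory=list)
    only_in_b: list = field(default_factory=list)
    changed: list = field(default_factory=list)
    measurement_deltas: list = field(default_factory=list)
    metadata_changes: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (
            self.only_in_a
            or self.only_in_b
            or self.changed
            or self.measurement_deltas
            or self.metadata_changes
        )


def _key(stmt: Statement) -> tuple:
    if isinstance(stmt, QualityStatement):
        return ("quality", canonical_path(stmt.subject))
    if isinstance(stmt, RelationalStatement):
        return ("relational", canonical_path(stmt.subject), stmt.relation.local_name)
    if isinstance(stmt, ComparativeStatement):
        return ("comparative", canonical_path(stmt.subject), stmt.attribute)
    if isinstance(stmt, MeasurementStatement):
        return ("measurement", canonical_path(stmt.subject), stmt.attribute)
    raise TypeError(f"not a diffable statement: {stmt!r}")


def _value(stmt: Statement) -> tuple:
    if isinstance(stmt, QualityStatement):
        return (stmt.quality.label,)
    if isinstance(stmt, RelationalStatement):
        attached = stmt.attached_quality.label if stmt.attached_quality else None
        return (canonical_path(stmt.object), attached)
    if isinstance(stmt, ComparativeStatement):
        return (stmt.comparator, stmt.reference_attribute, canonical_path(stmt.reference))
    if isinstance(stmt, MeasurementStatement):
        return (stmt.value, stmt.unit.label)
    raise TypeError


def _value_text(stmt: Statement) -> str:
    if isinstance(stmt, QualityStatement):
        return stmt.quality.label
    if isinstance(stmt, RelationalStatement):
        text = canonical_path(stmt.object)
        if stmt.attached_quality:
            text += f": {stmt.attached_quality.label}"
        return text
    if isinstance(stmt, ComparativeStatement):
        return (
            f"{stmt.comparator.replace('_', ' ')} {stmt.reference_attribute} "
            f"of {canonical_path(stmt.reference)}"
        )
    if isinstance(stmt, MeasurementStatement):
        return f"{stmt.value} {stmt.unit.label}"
    raise TypeError


def diff(a: SemanticDescription, b: SemanticDescription) -> DiffReport:
    """Compare two descriptions statement-by-statement."""
    if a.registry is not None and b.registry is not None and a.registry is not b.registry:
        raise RegistryMismatchError("descriptions were parsed against different registries")
    report = DiffReport()
    keys_a: dict[tuple, list[Statement]] = {}
    keys_b: dict[tuple, list[Statement]] = {}
    order: list[tuple] = []
    for stmt in a.statements:
        key = _key(stmt)
        if key not in keys_a and key not in keys_b:
            order.append(key)
        keys_a.setdefault(key, []).append(stmt)
    for stmt in b.statements:
        key = _key(stmt)
        if key not in keys_a and key not in keys_b:
            order.append(key)
        keys_b.setdefault(key, []).append(stmt)

    for key in order:
        in_a = list(keys_a.get(key, []))
        in_b = list(keys_b.get(key, []))
        # cancel identical statements pairwise
        rest_b = list(in_b)
        left_a = []
        for stmt in in_a:
            match = next((x for x in rest_b if _value(x) == _value(stmt)), None)
            if match is not None:
                rest_b.remove(match)
            else:
                left_a.append(stmt)
        left_b = rest_b
        kind = key[0]
        paired = min(len(left_a), len(left_b))
        for stmt_a, stmt_b in zip(left_a[:paired], left_b[:paired]):
            if kind == "measurement":
                report.measurement_deltas.append(
                    (key[1], key[2], stmt_a.value, stmt_b.value)
                )
            else:
                report.changed.append(
                    ChangedEntry(
                        path=key[1],
                        kind=kind,
                        attribute=key[2] if len(key) > 2 else None,
                        value_a=_value_text(stmt_a),
                        value_b=_value_text(stmt_b),
                        statement_a=stmt_a,
                        statement_b=stmt_b,
                    )
                )
        report.only_in_a.extend(left_a[paired:])
        report.only_in_b.extend(left_b[paired:])

    meta_a = {m.key: m.value for m in a.metadata}
    meta_b = {m.key: m.value for m in b.metadata}
    for key in list(meta_a) + [k for k in meta_b if k not in meta_a]:
        va, vb = meta_a.get(key), meta_b.get(key)
        if va != vb:
            report.metadata_changes.append((key, va, vb))
    return report


def summarize_diagnosis(report: DiffReport) -> list[str]:
    """One human-readable diagnostic line per difference, in report order."""
    lines: list[str] = []
    for entry in report.changed:
        lines.append(f"{entry.path}: {entry.value_a} (a) vs {entry.value_b} (b);")
    for stmt in report.only_in_a:
        lines.append(f"only in a: {render_statement(stmt)}")
    for stmt in report.only_in_b:
        lines.append(f"only in b: {render_statement(stmt)}")
    for path, attribute, value_a, value_b in report.measurement_deltas:
        lines.append(f"{path}: {attribute} {value_a} (a) vs {value_b} (b);")
    return lines
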