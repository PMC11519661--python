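"""Dichotomous identification keys: model, validation, traversal.

A key is a set of numbered couplets, each offering exactly two alternative
leads; a lead either names a terminal taxon or forwards to another
couplet.  This mirrors the tabular layout of published keys, where the
numbered row is the first lead and the dash row the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = [
    "Lead",
    "Couplet",
    "Key",
    "KeyError_",
    "InvalidChoiceError",
    "ChoicesExhaustedError",
    "validate_key",
    "evaluate",
    "enumerate_taxa",
    "load_key",
]


class KeyError_(ValueError):
    """Structural problem in a key definition."""


class InvalidChoiceError(ValueError):
    pass


class ChoicesExhaustedError(ValueError):
    pass


@dataclass(frozen=True)
class Lead:
    """One alternative of a couplet: character-state text plus a target."""

    text: str
    taxon: Optional[str] = None
    couplet: Optional[int] = None
    figure_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.taxon is None) == (self.couplet is None):
            raise KeyError_(
                f"a lead must target exactly one of taxon/couplet: {self.text[:40]!r}"
            )


@dataclass(frozen=True)
class Couplet:
    id: int
    leads: tuple[Lead, Lead]

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise KeyError_(f"couplet id must be positive, got {self.id}")
        if len(self.leads) != 2:
            raise KeyError_(f"couplet {self.id} must have exactly two leads")


@dataclass(frozen=True)
class Key:
    name: str
    root_id: int
    couplets: dict = field(default_factory=dict)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(enumerate_taxa(self))


def validate_key(key: Key) -> list[str]:
    """Structural issues: missing root, dangling targets, cycles, unreachable couplets."""
    issues: list[str] = []
    if key.root_id not in key.couplets:
        issues.append(f"root couplet {key.root_id} not present")
        return issues
    for couplet in key.couplets.values():
        for lead in couplet.leads:
            if lead.couplet is not None and lead.couplet not in key.couplets:
                issues.append(
                    f"couplet {couplet.id} targets missing couplet {lead.couplet}"
                )
    reachable: set[int] = set()

    def visit(cid: int, trail: tuple[int, ...]) -> None:
        if cid in trail:
            cycle = trail[trail.index(cid):] + (cid,)
            issues.append("cycle: " + " -> ".join(map(str, cycle)))
            return
        if cid not in key.couplets:
            return
        reachable.add(cid)
        for lead in key.couplets[cid].leads:
            if lead.couplet is not None:
                visit(lead.couplet, trail + (cid,))

    visit(key.root_id, ())
    for cid in sorted(key.couplets):
        if cid not in reachable:
            issues.append(f"couplet {cid} unreachable from root")
    return issues


def evaluate(key: Key, choices: Sequence[int]) -> str:
    """Follow 1-based lead choices from the root; return the taxon reached."""
    issues = validate_key(key)
    if issues:
        raise KeyError_("invalid key: " + "; ".join(issues))
    current = key.root_id
    for depth, choice in enumerate(choices):
        if choice not in (1, 2):
            raise InvalidChoiceError(f"choice {choice!r} at step {depth + 1} (expected 1 or 2)")
        lead = key.couplets[current].leads[choice - 1]
        if lead.taxon is not None:
            if depth + 1 != len(choices):
                raise InvalidChoiceError(
                    f"reached {lead.taxon!r} at step {depth + 1} but more choices remain"
                )
            return lead.taxon
        current = lead.couplet
    raise ChoicesExhaustedError(
        f"choices exhausted at couplet {current}; the path is not terminal"
    )


def enumerate_taxa(key: Key) -> set[str]:
    """All terminal taxa reachable from the root."""
    taxa: set[str] = set()
    seen: set[int] = set()
    stack = [key.root_id]
    while stack:
        cid = stack.pop()
        if cid in seen or cid not in key.couplets:
            continue
        seen.add(cid)
        for lead in key.couplets[cid].leads:
            if lead.taxon is not None:
                taxa.add(lead.taxon)
            else:
                stack.append(lead.couplet)
    return taxa


def _lead_from_dict(data: dict) -> Lead:
    return Lead(
        text=data.get("text", ""),
        taxon=data.get("taxon"),
        couplet=data.get("couplet"),
        figure_refs=tuple(data.get("figures", ())),
    )


def load_key(source: str | Path) -> Key:
    """Load a key from YAML (path or text)."""
    if isinstance(source, Path) or "\n" not in str(source):
        data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        data = yaml.safe_load(source)
    couplets: dict[int, Couplet] = {}
    for cid, leads in data["couplets"].items():
        cid = int(cid)
        if cid in couplets:
            raise KeyError_(f"duplicate couplet id {cid}")
        if len(leads) != 2:
            raise KeyError_(f"couplet {cid} must have exactly two leads")
        couplets[cid] = Couplet(cid, (_lead_from_dict(leads[0]), _lead_from_dict(leads[1])))
    return Key(
        name=data.get("name", ""),
        root_id=int(data.get("root", min(couplets, default=1))),
        couplets=couplets,
    )
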