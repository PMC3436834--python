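"""Core data model for multi-level event annotation.

An annotated document holds four kinds of annotation over a fixed text:

* entity mentions — continuous typed spans denoting continuants (organisms,
  anatomical entities, molecules);
* event triggers — typed spans stating that an event occurs;
* events — typed n-ary associations of a trigger with role-labelled
  arguments, each argument an entity or another event (so event structures
  nest recursively);
* modifications — binary Negation / Speculation flags on events.

Offsets are 0-based, half-open character offsets into the document text,
following the BioNLP shared-task standoff convention.  Entities and triggers
share the ``T`` id namespace; events use ``E``, modifications ``M``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TextSpan",
    "EntityMention",
    "EventTrigger",
    "EventArgument",
    "EventStructure",
    "EventModification",
    "AnnotatedDocument",
    "Corpus",
    "Violation",
    "BASE_ROLES",
    "REPEATABLE_ROLES",
    "split_role",
]

#: Base argument roles.  Only Theme is repeatable (Theme2, Theme3, ...).
BASE_ROLES = ("Theme", "Cause", "Site", "AtLoc", "FromLoc", "ToLoc", "Instrument")
REPEATABLE_ROLES = frozenset({"Theme"})

_ROLE_RE = re.compile(r"^([A-Za-z]+?)(\d*)$")


def split_role(role: str) -> tuple[str, int]:
    """Split a role label into its base role and ordinal.

    ``"Theme" -> ("Theme", 1)``, ``"Theme2" -> ("Theme", 2)``.
    """
    m = _ROLE_RE.match(role)
    if m is None:
        return role, 1
    base, ordinal = m.group(1), m.group(2)
    return base, int(ordinal) if ordinal else 1


@dataclass(frozen=True, order=True)
class TextSpan:
    """A continuous character span, 0-based and half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class EntityMention:
    id: str
    entity_type: str
    span: TextSpan
    surface: str


@dataclass(frozen=True)
class EventTrigger:
    id: str
    event_type: str
    span: TextSpan
    surface: str


@dataclass(frozen=True)
class EventArgument:
    """A role-labelled argument slot.

    ``target`` is an annotation id: ``T*`` for an entity mention, ``E*`` for
    a (sub-)event.  ``role`` may carry an ordinal suffix on repeatable roles
    (``Theme2``).
    """

    role: str
    target: str

    @property
    def base_role(self) -> str:
        return split_role(self.role)[0]

    @property
    def is_event_ref(self) -> bool:
        return self.target.startswith("E")


@dataclass(frozen=True)
class EventStructure:
    id: str
    event_type: str
    trigger: str  # EventTrigger id
    arguments: tuple[EventArgument, ...] = ()

    def args_with_base(self, base_role: str) -> tuple[EventArgument, ...]:
        return tuple(a for a in self.arguments if a.base_role == base_role)


@dataclass(frozen=True)
class EventModification:
    id: str
    kind: str  # Negation | Speculation
    target: str  # EventStructure id


MODIFICATION_KINDS = ("Negation", "Speculation")


@dataclass(frozen=True)
class Violation:
    """A validation finding: the offending annotation id and the broken rule."""

    annotation_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.annotation_id}: {self.message}"


#: Rules reported by validation but tolerated when serializing (predicted
#: output may legitimately drop low-confidence events, orphaning triggers).
WARNING_RULES = frozenset({"orphan-trigger"})


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: dict[str, EntityMention] = field(default_factory=dict)
    triggers: dict[str, EventTrigger] = field(default_factory=dict)
    events: dict[str, EventStructure] = field(default_factory=dict)
    modifications: dict[str, EventModification] = field(default_factory=dict)

    # -- convenience -----------------------------------------------------
    def resolve(self, ann_id: str):
        for coll in (self.entities, self.triggers, self.events, self.modifications):
            if ann_id in coll:
                return coll[ann_id]
        raise KeyError(ann_id)

    def textbound(self, ann_id: str):
        """Resolve a T id to its entity or trigger annotation."""
        if ann_id in self.entities:
            return self.entities[ann_id]
        return self.triggers[ann_id]

    def annotations_equal(self, other: "AnnotatedDocument") -> bool:
        """Equality on annotation content (ignores doc_id)."""
        return (
            self.text == other.text
            and self.entities == other.entities
            and self.triggers == other.triggers
            and self.events == other.events
            and self.modifications == other.modifications
        )

    def event_argument_graph(self) -> dict[str, list[str]]:
        """Adjacency event id -> referenced sub-event ids."""
        return {
            eid: [a.target for a in ev.arguments if a.is_event_ref]
            for eid, ev in self.events.items()
        }

    def modification_flags(self, event_id: str) -> frozenset[str]:
        return frozenset(
            m.kind for m in self.modifications.values() if m.target == event_id
        )


@dataclass
class Corpus:
    """Documents grouped into train / devel / test splits."""

    splits: dict[str, list[AnnotatedDocument]] = field(default_factory=dict)

    SPLIT_NAMES = ("train", "devel", "test")

    def documents(self, splits=None):
        names = self.SPLIT_NAMES if splits is None else splits
        for name in names:
            yield from self.splits.get(name, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.splits.values())


def _span_violations(doc: AnnotatedDocument, ann) -> list[Violation]:
    out = []
    if ann.span.end > len(doc.text):
        out.append(
            Violation(ann.id, "span-bounds", f"span {ann.span} exceeds text length {len(doc.text)}")
        )
        return out
    actual = doc.text[ann.span.start : ann.span.end]
    if actual != ann.surface:
        out.append(
            Violation(
                ann.id,
                "surface-integrity",
                f"surface {ann.surface!r} != text at offsets {actual!r}",
            )
        )
    return out


def validate_document(doc: AnnotatedDocument, schema=None) -> list[Violation]:
    """Check every structural invariant; return findings (never raise).

    With a :class:`~mlevent.schema.TaskSchema` supplied, type names and
    role/category constraints are checked as well.
    """
    violations: list[Violation] = []

    for ent in doc.entities.values():
        violations += _span_violations(doc, ent)
    for trg in doc.triggers.values():
        violations += _span_violations(doc, trg)

    referenced_triggers: set[str] = set()
    for ev in doc.events.values():
        if ev.trigger not in doc.triggers:
            violations.append(
                Violation(ev.id, "dangling-trigger", f"trigger {ev.trigger} not declared")
            )
        else:
            referenced_triggers.add(ev.trigger)
            if doc.triggers[ev.trigger].event_type != ev.event_type:
                violations.append(
                    Violation(
                        ev.id,
                        "trigger-type-mismatch",
                        f"event type {ev.event_type} != trigger type "
                        f"{doc.triggers[ev.trigger].event_type}",
                    )
                )
        seen_roles: set[str] = set()
        for arg in ev.arguments:
            base, ordinal = split_role(arg.role)
            if base not in BASE_ROLES:
                violations.append(Violation(ev.id, "unknown-role", f"role {arg.role}"))
            if ordinal > 1 and base not in REPEATABLE_ROLES:
                violations.append(
                    Violation(ev.id, "role-not-repeatable", f"role {arg.role}")
                )
            if arg.role in seen_roles:
                violations.append(Violation(ev.id, "duplicate-role", f"role {arg.role}"))
            seen_roles.add(arg.role)
            if arg.is_event_ref:
                if arg.target not in doc.events:
                    violations.append(
                        Violation(ev.id, "dangling-argument", f"event {arg.target}")
                    )
                if arg.target == ev.id:
                    violations.append(Violation(ev.id, "self-reference", "event is its own argument"))
            elif arg.target not in doc.entities:
                violations.append(
                    Violation(ev.id, "dangling-argument", f"entity {arg.target}")
                )

    # acyclicity over the event-argument graph (self loops reported above)
    graph = doc.event_argument_graph()
    state: dict[str, int] = {}

    def has_cycle(node: str) -> bool:
        state[node] = 1
        for nxt in graph.get(node, ()):
            if nxt == node or nxt not in graph:
                continue
            s = state.get(nxt, 0)
            if s == 1 or (s == 0 and has_cycle(nxt)):
                return True
        state[node] = 2
        return False

    for eid in graph:
        if state.get(eid, 0) == 0 and has_cycle(eid):
            violations.append(Violation(eid, "cyclic-reference", "event argument cycle"))

    per_event_kinds: dict[str, set[str]] = {}
    for mod in doc.modifications.values():
        if mod.kind not in MODIFICATION_KINDS:
            violations.append(Violation(mod.id, "unknown-modification", mod.kind))
        if mod.target not in doc.events:
            violations.append(
                Violation(mod.id, "dangling-modification", f"event {mod.target}")
            )
        kinds = per_event_kinds.setdefault(mod.target, set())
        if mod.kind in kinds:
            violations.append(
                Violation(mod.id, "duplicate-modification", f"{mod.kind} on {mod.target}")
            )
        kinds.add(mod.kind)

    for tid in doc.triggers:
        if tid not in referenced_triggers:
            violations.append(Violation(tid, "orphan-trigger", "trigger anchors no event"))

    if schema is not None:
        for ev in doc.events.values():
            violations += schema.validate_event(ev, doc)
        for ent in doc.entities.values():
            if ent.entity_type not in schema.entity_types:
                violations.append(
                    Violation(ent.id, "unknown-entity-type", ent.entity_type)
                )
        for trg in doc.triggers.values():
            if trg.event_type not in schema.event_types:
                violations.append(Violation(trg.id, "unknown-event-type", trg.event_type))

    return violations


def hard_violations(violations: list[Violation]) -> list[Violation]:
    return [v for v in violations if v.rule not in WARNING_RULES]
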