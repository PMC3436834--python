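"""The MLEE type system.

14 entity types partitioned into three informal evaluation categories
(Organism / Anatomy / Molecule) and 19 event types partitioned into four
(Anatomical / Molecular / General / Planned), together with the argument
roles each event type admits and the category restriction on entity-valued
Themes: Anatomical events involve Organism or Anatomy entities, Molecular
events involve Molecule entities, the rest are unrestricted.  Event-valued
Themes (regulation of other events) are never restricted.

The schema is declarative — shipped as a YAML file so alternative task
schemas can be dropped in — and loaded once at import.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .model import AnnotatedDocument, EventStructure, Violation, split_role

__all__ = [
    "EntityTypeInfo",
    "EventTypeInfo",
    "TaskSchema",
    "SchemaError",
    "load_schema",
    "default_schema",
]


class SchemaError(KeyError):
    """An unknown type name was queried against the schema."""


@dataclass(frozen=True)
class EntityTypeInfo:
    name: str
    category: str
    ontology_refs: tuple[str, ...] = ()


@dataclass(frozen=True)
class EventTypeInfo:
    name: str
    category: str
    allowed_roles: frozenset[str]
    theme_constraint: frozenset[str] | None  # entity categories, None = unrestricted
    ontology_refs: tuple[str, ...] = ()


class TaskSchema:
    def __init__(
        self,
        entity_types: dict[str, EntityTypeInfo],
        event_types: dict[str, EventTypeInfo],
    ):
        self.entity_types = entity_types
        self.event_types = event_types

    # -- lookups ---------------------------------------------------------
    def entity_category(self, entity_type: str) -> str:
        try:
            return self.entity_types[entity_type].category
        except KeyError:
            raise SchemaError(f"unknown entity type {entity_type!r}") from None

    def event_category(self, event_type: str) -> str:
        try:
            return self.event_types[event_type].category
        except KeyError:
            raise SchemaError(f"unknown event type {event_type!r}") from None

    def allowed_roles(self, event_type: str) -> frozenset[str]:
        try:
            return self.event_types[event_type].allowed_roles
        except KeyError:
            raise SchemaError(f"unknown event type {event_type!r}") from None

    def theme_constraint(self, event_type: str) -> frozenset[str] | None:
        try:
            return self.event_types[event_type].theme_constraint
        except KeyError:
            raise SchemaError(f"unknown event type {event_type!r}") from None

    @property
    def entity_categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for info in self.entity_types.values():
            seen.setdefault(info.category)
        return tuple(seen)

    @property
    def event_categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for info in self.event_types.values():
            seen.setdefault(info.category)
        return tuple(seen)

    # -- validation ------------------------------------------------------
    def validate_event(
        self, event: EventStructure, doc: AnnotatedDocument
    ) -> list[Violation]:
        """Schema-level checks: allowed roles and Theme category restriction.

        Structural problems (dangling references etc.) are the business of
        :func:`mlevent.model.validate_document`; dangling targets are simply
        skipped here.
        """
        violations: list[Violation] = []
        if event.event_type not in self.event_types:
            violations.append(
                Violation(event.id, "unknown-event-type", event.event_type)
            )
            return violations
        info = self.event_types[event.event_type]
        for arg in event.arguments:
            base, _ = split_role(arg.role)
            if base not in info.allowed_roles:
                violations.append(
                    Violation(
                        event.id,
                        "role-not-allowed",
                        f"{event.event_type} does not take {base} "
                        f"(allows {sorted(info.allowed_roles)})",
                    )
                )
                continue
            if (
                base == "Theme"
                and info.theme_constraint is not None
                and not arg.is_event_ref
                and arg.target in doc.entities
            ):
                cat = self.entity_category(doc.entities[arg.target].entity_type)
                if cat not in info.theme_constraint:
                    violations.append(
                        Violation(
                            event.id,
                            "theme-category",
                            f"{info.category} event takes {sorted(info.theme_constraint)} "
                            f"Themes, got {cat} entity {arg.target}",
                        )
                    )
        return violations


def load_schema(source) -> TaskSchema:
    """Build a TaskSchema from a YAML mapping (path, file object or dict)."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)

    entity_types = {
        e["name"]: EntityTypeInfo(
            e["name"], e["category"], tuple(e.get("ontology_refs", ()))
        )
        for e in raw["entity_types"]
    }
    constraints = raw.get("theme_constraints", {})
    event_types = {}
    for e in raw["event_types"]:
        roles = frozenset(e["roles"])
        if "Theme" not in roles:
            raise ValueError(f"event type {e['name']} must allow Theme")
        restriction = constraints.get(e["category"])
        event_types[e["name"]] = EventTypeInfo(
            e["name"],
            e["category"],
            roles,
            frozenset(restriction) if restriction is not None else None,
            tuple(e.get("ontology_refs", ())),
        )
    return TaskSchema(entity_types, event_types)


_DEFAULT: TaskSchema | None = None


def default_schema() -> TaskSchema:
    """The MLEE schema shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("mlevent.data").joinpath("mlee_schema.yaml")
        with ref.open(encoding="utf-8") as fh:
            _DEFAULT = load_schema(fh)
    return _DEFAULT


# Module-level convenience mirroring the common call sites.
def entity_category(entity_type: str) -> str:
    return default_schema().entity_category(entity_type)


def allowed_roles(event_type: str) -> frozenset[str]:
    return default_schema().allowed_roles(event_type)


def validate_event_against_schema(
    event: EventStructure, doc: AnnotatedDocument
) -> list[Violation]:
    return default_schema().validate_event(event, doc)
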