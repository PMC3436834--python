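"""Reading and writing BioNLP-style standoff annotation.

Dialect:

* ``.a1`` holds entity lines only::

      T1<TAB>Multi-tissue structure 0 12<TAB>blood vessel

* ``.a2`` holds trigger lines (same shape as entity lines), event lines and
  modification lines::

      T2<TAB>Development 13 24<TAB>development
      E1<TAB>Development:T2 Theme:T1
      M1<TAB>Negation E1

MLEE type names may contain spaces, so the type/offset field is split from
the right (the last two tokens are the offsets) and event lines scan for the
first ``:`` to terminate the multi-word type.  Relation (``R``),
equivalence (``*``) and normalization (``N``) lines are out of scope and
rejected.
"""

from __future__ import annotations

import os
from pathlib import Path

from .model import (
    AnnotatedDocument,
    Corpus,
    EntityMention,
    EventArgument,
    EventModification,
    EventStructure,
    EventTrigger,
    TextSpan,
    hard_violations,
    validate_document,
)

__all__ = [
    "StandoffParseError",
    "SpanIntegrityError",
    "AnnotationReferenceError",
    "DocumentValidationError",
    "parse_standoff",
    "write_standoff",
    "read_document",
    "write_document",
    "read_corpus",
    "write_corpus",
]


class StandoffParseError(ValueError):
    def __init__(self, filename: str, line_no: int, reason: str):
        super().__init__(f"{filename}:{line_no}: {reason}")
        self.filename, self.line_no, self.reason = filename, line_no, reason


class SpanIntegrityError(ValueError):
    """Annotation surface string disagrees with the text at its offsets."""


class AnnotationReferenceError(ValueError):
    """An annotation references an id that is not declared."""


class DocumentValidationError(ValueError):
    def __init__(self, violations):
        super().__init__(
            "invalid document: " + "; ".join(str(v) for v in violations)
        )
        self.violations = violations


def _id_number(ann_id: str) -> int:
    return int(ann_id[1:])


def _parse_textbound(filename: str, line_no: int, line: str):
    fields = line.split("\t")
    if len(fields) != 3:
        raise StandoffParseError(
            filename, line_no, f"expected 3 tab-separated fields, got {len(fields)}"
        )
    ann_id, type_and_span, surface = fields
    parts = type_and_span.rsplit(" ", 2)
    if len(parts) != 3:
        raise StandoffParseError(filename, line_no, "expected '<type> <start> <end>'")
    type_name, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise StandoffParseError(
            filename, line_no, f"non-integer offsets {start_s!r} {end_s!r}"
        ) from None
    if not 0 <= start < end:
        raise StandoffParseError(filename, line_no, f"bad span ({start}, {end})")
    return ann_id, type_name, TextSpan(start, end), surface


def _check_surface(text: str, ann_id: str, span: TextSpan, surface: str) -> None:
    if span.end > len(text):
        raise SpanIntegrityError(
            f"{ann_id}: span {span} beyond text length {len(text)}"
        )
    actual = text[span.start : span.end]
    if actual != surface:
        raise SpanIntegrityError(
            f"{ann_id}: surface {surface!r} != text {actual!r} at {span}"
        )


def _parse_event_body(filename: str, line_no: int, body: str):
    """Split ``Blood vessel development:T2 Theme:T1 ...`` into type, trigger, args."""
    tokens = body.split(" ")
    type_words: list[str] = []
    trigger_id = None
    rest_start = 0
    for i, tok in enumerate(tokens):
        if ":" in tok:
            head, _, trigger_id = tok.rpartition(":")
            type_words.append(head)
            rest_start = i + 1
            break
        type_words.append(tok)
    if trigger_id is None or not trigger_id:
        raise StandoffParseError(filename, line_no, "missing '<type>:<trigger>' head")
    args = []
    for tok in tokens[rest_start:]:
        if not tok:
            continue
        role, sep, target = tok.partition(":")
        if not sep or not role or not target:
            raise StandoffParseError(filename, line_no, f"malformed argument {tok!r}")
        args.append(EventArgument(role=role, target=target))
    return " ".join(type_words), trigger_id, tuple(args)


def parse_standoff(
    text: str, a1: str, a2: str, doc_id: str = "doc"
) -> AnnotatedDocument:
    """Parse standoff annotation content against its document text.

    Raises :class:`StandoffParseError` on malformed lines (naming line and
    reason), :class:`SpanIntegrityError` on offset/surface disagreement and
    :class:`AnnotationReferenceError` on unresolvable references.
    """
    doc = AnnotatedDocument(doc_id=doc_id, text=text)

    def seen(ann_id: str) -> bool:
        return (
            ann_id in doc.entities
            or ann_id in doc.triggers
            or ann_id in doc.events
            or ann_id in doc.modifications
        )

    for line_no, line in enumerate(a1.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            raise StandoffParseError(
                ".a1", line_no, f"only entity (T) lines allowed, got {line[:1]!r}"
            )
        ann_id, type_name, span, surface = _parse_textbound(".a1", line_no, line)
        if seen(ann_id):
            raise StandoffParseError(".a1", line_no, f"duplicate id {ann_id}")
        _check_surface(text, ann_id, span, surface)
        doc.entities[ann_id] = EntityMention(ann_id, type_name, span, surface)

    event_lines: list[tuple[int, str]] = []
    mod_lines: list[tuple[int, str]] = []
    for line_no, line in enumerate(a2.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            ann_id, type_name, span, surface = _parse_textbound(".a2", line_no, line)
            if seen(ann_id):
                raise StandoffParseError(".a2", line_no, f"duplicate id {ann_id}")
            _check_surface(text, ann_id, span, surface)
            doc.triggers[ann_id] = EventTrigger(ann_id, type_name, span, surface)
        elif line.startswith("E"):
            event_lines.append((line_no, line))
        elif line.startswith("M"):
            mod_lines.append((line_no, line))
        else:
            raise StandoffParseError(
                ".a2", line_no, f"unsupported line type {line[:1]!r}"
            )

    for line_no, line in event_lines:
        ann_id, tab, body = line.partition("\t")
        if not tab:
            raise StandoffParseError(".a2", line_no, "expected '<id><TAB><body>'")
        if seen(ann_id):
            raise StandoffParseError(".a2", line_no, f"duplicate id {ann_id}")
        event_type, trigger_id, args = _parse_event_body(".a2", line_no, body)
        doc.events[ann_id] = EventStructure(ann_id, event_type, trigger_id, args)

    for line_no, line in mod_lines:
        ann_id, tab, body = line.partition("\t")
        parts = body.split(" ")
        if not tab or len(parts) != 2:
            raise StandoffParseError(".a2", line_no, "expected '<id><TAB><kind> <event>'")
        if seen(ann_id):
            raise StandoffParseError(".a2", line_no, f"duplicate id {ann_id}")
        kind, target = parts
        doc.modifications[ann_id] = EventModification(ann_id, kind, target)

    # reference resolution
    for ev in doc.events.values():
        if ev.trigger not in doc.triggers:
            raise AnnotationReferenceError(
                f"{ev.id}: trigger {ev.trigger} not declared"
            )
        for arg in ev.arguments:
            pool = doc.events if arg.is_event_ref else doc.entities
            if arg.target not in pool:
                raise AnnotationReferenceError(
                    f"{ev.id}: argument {arg.role}:{arg.target} not declared"
                )
    for mod in doc.modifications.values():
        if mod.target not in doc.events:
            raise AnnotationReferenceError(
                f"{mod.id}: event {mod.target} not declared"
            )
    return doc


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a document to ``(a1, a2)`` content, ids in numeric order.

    Raises :class:`DocumentValidationError` when the document breaks a hard
    invariant (orphan triggers are tolerated here; dropping them is the
    producer's decision, not the serializer's).
    """
    bad = hard_violations(validate_document(doc))
    if bad:
        raise DocumentValidationError(bad)

    a1_lines = [
        f"{e.id}\t{e.entity_type} {e.span.start} {e.span.end}\t{e.surface}"
        for e in sorted(doc.entities.values(), key=lambda e: _id_number(e.id))
    ]
    a2_lines = [
        f"{t.id}\t{t.event_type} {t.span.start} {t.span.end}\t{t.surface}"
        for t in sorted(doc.triggers.values(), key=lambda t: _id_number(t.id))
    ]
    for ev in sorted(doc.events.values(), key=lambda e: _id_number(e.id)):
        body = f"{ev.event_type}:{ev.trigger}"
        for arg in ev.arguments:
            body += f" {arg.role}:{arg.target}"
        a2_lines.append(f"{ev.id}\t{body}")
    for mod in sorted(doc.modifications.values(), key=lambda m: _id_number(m.id)):
        a2_lines.append(f"{mod.id}\t{mod.kind} {mod.target}")

    join = lambda lines: "".join(line + "\n" for line in lines)
    return join(a1_lines), join(a2_lines)


# -- corpus directory layout: <split>/<docid>.{txt,a1,a2} ----------------


def read_document(txt_path: str | Path) -> AnnotatedDocument:
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    a1_path = txt_path.with_suffix(".a1")
    a2_path = txt_path.with_suffix(".a2")
    a1 = a1_path.read_text(encoding="utf-8") if a1_path.exists() else ""
    a2 = a2_path.read_text(encoding="utf-8") if a2_path.exists() else ""
    return parse_standoff(text, a1, a2, doc_id=txt_path.stem)


def write_document(doc: AnnotatedDocument, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    a1, a2 = write_standoff(doc)
    (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    (directory / f"{doc.doc_id}.a1").write_text(a1, encoding="utf-8")
    (directory / f"{doc.doc_id}.a2").write_text(a2, encoding="utf-8")


def read_corpus(directory: str | Path) -> Corpus:
    """Read a ``<split>/<docid>.{txt,a1,a2}`` corpus directory.

    A flat directory of documents (no split subdirectories) is read as a
    single ``train`` split.
    """
    directory = Path(directory)
    corpus = Corpus()
    split_dirs = [d for d in Corpus.SPLIT_NAMES if (directory / d).is_dir()]
    if split_dirs:
        for split in split_dirs:
            docs = [
                read_document(p)
                for p in sorted((directory / split).glob("*.txt"))
            ]
            corpus.splits[split] = docs
    else:
        corpus.splits["train"] = [
            read_document(p) for p in sorted(directory.glob("*.txt"))
        ]
    return corpus


def write_corpus(corpus: Corpus, directory: str | Path) -> None:
    directory = Path(directory)
    for split, docs in corpus.splits.items():
        for doc in docs:
            write_document(doc, os.path.join(directory, split))
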