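"""Standoff parsing, serialization and structural validation."""

import pytest

from mlevent.model import EventArgument, TextSpan, validate_document
from mlevent.standoff import (
    AnnotationReferenceError,
    DocumentValidationError,
    SpanIntegrityError,
    StandoffParseError,
    parse_standoff,
    write_standoff,
)

TEXT = "blood vessel development"
A1 = "T1\tMulti-tissue structure 0 12\tblood vessel\n"
A2 = "T2\tDevelopment 13 24\tdevelopment\nE1\tDevelopment:T2 Theme:T1\n"


def test_parse_entity_trigger_event():
    doc = parse_standoff(TEXT, A1, A2)
    assert len(doc.entities) == 1
    assert len(doc.triggers) == 1
    assert len(doc.events) == 1
    ent = doc.entities["T1"]
    assert ent.entity_type == "Multi-tissue structure"
    assert ent.span == TextSpan(0, 12)
    assert ent.surface == "blood vessel"
    ev = doc.events["E1"]
    assert ev.event_type == "Development"
    assert ev.trigger == "T2"
    assert ev.arguments == (EventArgument("Theme", "T1"),)
    assert validate_document(doc) == []


def test_parse_empty_annotation():
    doc = parse_standoff("any text at all", "", "")
    assert not doc.entities and not doc.triggers and not doc.events


def test_unresolvable_reference_raises():
    with pytest.raises(AnnotationReferenceError):
        parse_standoff(TEXT, A1, "E1\tGrowth:T9 Theme:T1\n")


def test_surface_mismatch_raises():
    with pytest.raises(SpanIntegrityError):
        parse_standoff(TEXT, "T1\tCell 0 5\twrong\n", "")


@pytest.mark.parametrize(
    "a1",
    [
        "T1\tCell 0\tblood\n",  # missing offset
        "T1 Cell 0 5 blood\n",  # no tabs
        "E1\tCell 0 5\tblood\n",  # event line in .a1
        "T1\tCell five 9\tblood\n",  # non-integer offsets
    ],
)
def test_malformed_a1_lines_raise_with_line_number(a1):
    with pytest.raises(StandoffParseError) as exc:
        parse_standoff(TEXT, a1, "")
    assert exc.value.line_no == 1


def test_duplicate_id_rejected():
    with pytest.raises(StandoffParseError):
        parse_standoff(TEXT, A1 + "T1\tCell 13 24\tdevelopment\n", "")


def test_round_trip_identity():
    doc = parse_standoff(TEXT, A1, A2)
    a1, a2 = write_standoff(doc)
    again = parse_standoff(TEXT, a1, a2)
    assert doc.annotations_equal(again)
    assert sorted(a1.splitlines()) == sorted(A1.splitlines())
    assert sorted(a2.splitlines()) == sorted(A2.splitlines())


def test_negation_line_format(build):
    b = build("cells did not proliferate")
    b.entity("T1", "Cell", 0, 5)
    b.trigger("T2", "Cell proliferation", 14, 25)
    b.event("E1", "Cell proliferation", "T2", ("Theme", "T1"))
    b.modify("M1", "Negation", "E1")
    _, a2 = write_standoff(b.doc)
    assert "M1\tNegation E1" in a2.splitlines()


def test_two_themes_serialize_with_ordinal(build):
    b = build("binding of VEGF and KDR")
    b.entity("T1", "Gene or gene product", 11, 15)
    b.entity("T2", "Gene or gene product", 20, 23)
    b.trigger("T3", "Binding", 0, 7)
    b.event("E1", "Binding", "T3", ("Theme", "T1"), ("Theme2", "T2"))
    _, a2 = write_standoff(b.doc)
    assert "E1\tBinding:T3 Theme:T1 Theme2:T2" in a2.splitlines()


def test_write_rejects_invalid_document(build):
    b = build("growth")
    b.trigger("T1", "Growth", 0, 6)
    b.event("E1", "Growth", "T1", ("Theme", "T99"))  # dangling
    with pytest.raises(DocumentValidationError):
        write_standoff(b.doc)


def test_validate_reports_cycle(build):
    b = build("inhibition of activation")
    b.trigger("T1", "Negative regulation", 0, 10)
    b.trigger("T2", "Positive regulation", 14, 24)
    b.event("E1", "Negative regulation", "T1", ("Theme", "E2"))
    b.event("E2", "Positive regulation", "T2", ("Theme", "E1"))
    rules = [v.rule for v in validate_document(b.doc)]
    assert rules.count("cyclic-reference") == 1


def test_validate_reports_surface_integrity(build):
    b = build("tumour growth")
    b.trigger("T1", "Growth", 0, 6)  # surface says "tumour", not a Growth word
    b.doc.triggers["T1"] = b.doc.triggers["T1"].__class__(
        "T1", "Growth", TextSpan(0, 6), "growth"
    )
    b.event("E1", "Growth", "T1")
    rules = [v.rule for v in validate_document(b.doc)]
    assert "surface-integrity" in rules


def test_orphan_trigger_flagged_but_serializable(build):
    b = build("growth was observed")
    b.trigger("T1", "Growth", 0, 6)
    rules = [v.rule for v in validate_document(b.doc)]
    assert rules == ["orphan-trigger"]
    a1, a2 = write_standoff(b.doc)  # warning-level: still serializes
    assert "T1\tGrowth 0 6\tgrowth" in a2.splitlines()


def test_round_trip_over_generated_corpus(small_corpus):
    """parse(write(doc)) preserves all annotation content, corpus-wide."""
    for doc in small_corpus.documents():
        a1, a2 = write_standoff(doc)
        again = parse_standoff(doc.text, a1, a2, doc.doc_id)
        assert doc.annotations_equal(again)
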