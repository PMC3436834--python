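"""Synthetic corpus generator: determinism, validity, distributions."""

import numpy as np
import pytest

from mlevent.evaluation import (
    EventCriteria,
    corpus_stats,
    cross_level_fraction,
    evaluate_events,
    evaluate_ner,
)
from mlevent.model import validate_document
from mlevent.schema import default_schema
from mlevent.standoff import write_standoff
from mlevent.synth import (
    GeneratorConfig,
    fixture_tables,
    generate_corpus,
    generate_lexicons,
)


def test_generation_is_deterministic_byte_identical():
    a = generate_corpus(GeneratorConfig(seed=9, n_documents=12))
    b = generate_corpus(GeneratorConfig(seed=9, n_documents=12))
    for da, db in zip(a.documents(), b.documents()):
        assert da.text == db.text
        assert write_standoff(da) == write_standoff(db)


def test_default_corpus_parses_and_has_all_entity_categories():
    corpus = generate_corpus(GeneratorConfig(seed=1, n_documents=50))
    schema = default_schema()
    for doc in corpus.documents():
        assert validate_document(doc, schema) == []
    stats = corpus_stats(corpus)
    assert all(v > 0 for v in stats["total"]["entities_by_category"].values())
    assert stats["total"]["events"] > 0


def test_split_proportions_and_membership():
    corpus = generate_corpus(GeneratorConfig(seed=4, n_documents=60))
    sizes = {s: len(d) for s, d in corpus.splits.items()}
    assert sum(sizes.values()) == 60
    assert sizes["train"] > sizes["test"] > sizes["devel"]
    ids = [d.doc_id for d in corpus.documents()]
    assert len(ids) == len(set(ids))


def test_cross_level_rate_zero_realizes_zero():
    corpus = generate_corpus(
        GeneratorConfig(seed=2, n_documents=30, cross_level_rate=0.0)
    )
    assert cross_level_fraction(corpus) == 0.0


def test_cross_level_calibration(bench_corpus):
    """Realized fraction within ±0.03 of the configured 0.18 default."""
    n_events = sum(len(d.events) for d in bench_corpus.documents())
    assert n_events >= 500
    assert cross_level_fraction(bench_corpus) == pytest.approx(0.18, abs=0.03)


def test_event_category_proportions_match_weights(bench_corpus, bench_config):
    """Each event-category proportion within 3 standard errors of target."""
    schema = default_schema()
    target = {c: 0.0 for c in schema.event_categories}
    total_w = sum(bench_config.event_type_weights.values())
    for t, w in bench_config.event_type_weights.items():
        target[schema.event_category(t)] += w / total_w
    counts = corpus_stats(bench_corpus)["total"]["events_by_category"]
    n = sum(counts.values())
    assert n >= 500
    for cat, p in target.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[cat] / n - p) <= 3 * se, cat


def test_self_evaluation_is_perfect(small_corpus):
    docs = list(small_corpus.documents())
    for crit in ("exact", "left", "right"):
        assert evaluate_ner(docs, docs, crit).overall.f_score == 100.0
    for criteria in (EventCriteria(False, False), EventCriteria(True, True)):
        report = evaluate_events(docs, docs, criteria)
        assert report.overall.f_score == 100.0
        assert report.extra["Modification"].fp == 0
        assert report.extra["Modification"].fn == 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        generate_corpus(GeneratorConfig(seed=1, cross_level_rate=1.5))
    with pytest.raises(ValueError):
        generate_corpus(
            GeneratorConfig(seed=1, event_type_weights={"Growth": -1.0})
        )
    with pytest.raises(ValueError):
        generate_corpus(
            GeneratorConfig(seed=1, event_type_weights={"Mitosis": 1.0})
        )


def test_lexicon_full_coverage(small_corpus):
    config = GeneratorConfig(seed=5, n_documents=30, lexicon_coverage=1.0)
    lexicons = generate_lexicons(config, small_corpus)
    schema = default_schema()
    from mlevent.ner import _normalize

    for doc in small_corpus.documents():
        for ent in doc.entities.values():
            cat = schema.entity_category(ent.entity_type)
            assert _normalize(ent.surface) in lexicons[cat].entries


def test_lexicon_zero_coverage_only_distractors(small_corpus):
    config = GeneratorConfig(seed=5, n_documents=30, lexicon_coverage=0.0)
    lexicons = generate_lexicons(config, small_corpus)
    schema = default_schema()
    from mlevent.ner import _normalize

    gold_surfaces = {
        _normalize(e.surface)
        for d in small_corpus.documents()
        for e in d.entities.values()
    }
    for lex in lexicons.values():
        assert len(lex) > 0
        assert not (lex.entries & gold_surfaces)


def test_fixture_tables_expose_published_rows():
    tables = fixture_tables()
    assert tables["ner_overall"]["base"]["exact"][:2] == (77.03, 69.18)
    assert tables["corpus_stats"]["Event"] == (3296, 1175, 2206, 6677)
    assert tables["event_by_category"]["Anatomical"][:2] == (80.91, 72.05)


def test_modifications_generated_at_configured_rates(bench_corpus):
    stats = corpus_stats(bench_corpus)["total"]
    assert stats["modifications"] > 0
    # both kinds occur
    kinds = {
        m.kind for d in bench_corpus.documents() for m in d.modifications.values()
    }
    assert kinds == {"Negation", "Speculation"}
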