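"""Tokenization, BIO encoding, lexicon matching and the mention detector."""

import pytest

from mlevent.model import AnnotatedDocument, Corpus, EntityMention, TextSpan
from mlevent.ner import (
    Lexicon,
    decode_bio,
    encode_bio,
    lexicon_match,
    predict_entities,
    token_features,
    train_ner,
)
from mlevent.standoff import write_standoff
from mlevent.tokenize import segment, tokenize_sentence


# -- segmentation --------------------------------------------------------


def test_segment_simple_sentence():
    sents = segment("VEGF induces angiogenesis.")
    assert len(sents) == 1
    toks = sents[0]
    assert [t.surface for t in toks] == ["VEGF", "induces", "angiogenesis", "."]
    assert toks[0].span == TextSpan(0, 4)
    assert toks[2].span == TextSpan(13, 25)


def test_segment_empty_string():
    assert segment("") == []


def test_abbreviation_does_not_split():
    assert len(segment("E. coli grows.")) == 1
    assert len(segment("Cells proliferate. Vessels grow.")) == 2


def test_token_spans_tile_nonwhitespace():
    text = "Inhibition of NO synthase by L-NAME (10 mg/kg)."
    covered = set()
    for sent in segment(text):
        for tok in sent:
            covered.update(range(tok.span.start, tok.span.end))
    expected = {i for i, c in enumerate(text) if not c.isspace()}
    assert covered == expected


# -- BIO encode / decode -------------------------------------------------


def _doc_with(text, entities):
    doc = AnnotatedDocument(doc_id="d", text=text)
    for i, (etype, start, end) in enumerate(entities, 1):
        doc.entities[f"T{i}"] = EntityMention(
            f"T{i}", etype, TextSpan(start, end), text[start:end]
        )
    return doc


def test_encode_multiword_entity():
    text = "proliferating endothelial cells were seen"
    doc = _doc_with(text, [("Cell", 14, 31)])
    sents = segment(text)
    labels = encode_bio(doc, sents)
    assert labels[0] == ["O", "B-Cell", "I-Cell", "O", "O"]


def test_encode_no_entities_all_outside():
    text = "nothing to see here"
    assert encode_bio(_doc_with(text, []), segment(text)) == [["O"] * 4]


def test_nested_entity_longest_span_wins():
    text = "tumor cells proliferate"
    doc = _doc_with(text, [("Cell", 0, 11), ("Pathological formation", 0, 5)])
    labels = encode_bio(doc, segment(text))
    assert labels[0] == ["B-Cell", "I-Cell", "O"]


def test_encode_decode_inverse_on_generated_docs(small_corpus):
    """Decoding recovers exactly the encodable entities."""
    for doc in small_corpus.documents():
        sents = segment(doc.text)
        decoded = decode_bio(doc.text, sents, encode_bio(doc, sents))
        got = {(e.entity_type, e.span.start, e.span.end) for e in decoded}
        want = {
            (e.entity_type, e.span.start, e.span.end) for e in doc.entities.values()
        }
        assert got == want


def test_decode_repairs_dangling_inside_label():
    text = "human endothelial cells"
    sents = segment(text)
    ents = decode_bio(text, sents, [["O", "I-Cell", "I-Cell"]])
    assert len(ents) == 1
    assert ents[0].span == TextSpan(6, 23)


# -- lexicon matching ----------------------------------------------------


def test_longest_entry_wins():
    lex = Lexicon.from_surfaces("Cell", ["endothelial cells", "cells"])
    toks = tokenize_sentence("human umbilical vein endothelial cells")
    assert lexicon_match(toks, lex) == [(3, 5)]


def test_empty_lexicon_no_matches():
    toks = tokenize_sentence("anything at all")
    assert lexicon_match(toks, Lexicon.from_surfaces("x", [])) == []


def test_matching_is_case_insensitive_and_punctuation_folded():
    lex = Lexicon.from_surfaces("Molecule", ["TNF-alpha"])
    toks = tokenize_sentence("tnf alpha levels rose")
    assert lexicon_match(toks, lex) == [(0, 2)]


def _oracle_leftmost_longest(words, entries):
    """Independent greedy definition: repeatedly take the longest entry
    starting at the leftmost matchable position."""
    out, i = [], 0
    while i < len(words):
        best = 0
        for length in range(len(words) - i, 0, -1):
            if tuple(words[i : i + length]) in entries:
                best = length
                break
        if best:
            out.append((i, i + best))
            i += best
        else:
            i += 1
    return out


def test_greedy_matches_oracle_on_random_streams():
    import numpy as np

    rng = np.random.default_rng(0)
    vocab = ["alpha", "beta", "gamma", "delta", "cell", "factor"]
    for _ in range(50):
        words = [vocab[i] for i in rng.integers(0, len(vocab), size=12)]
        entries = set()
        for _ in range(5):
            j = int(rng.integers(0, 11))
            k = int(rng.integers(1, 4))
            entries.add(tuple(words[j : j + k]))
        lex = Lexicon("x", frozenset(entries))
        toks = tokenize_sentence(" ".join(words))
        got = lexicon_match(toks, lex)
        assert got == _oracle_leftmost_longest(words, entries)


# -- features ------------------------------------------------------------


def test_allcaps_shape_feature():
    toks = tokenize_sentence("VEGF")
    assert "allcaps" in token_features(toks)[0]


def test_no_dictionary_feature_without_entry():
    toks = tokenize_sentence("angiogenesis")
    lex = Lexicon.from_surfaces("Anatomy", ["retina"])
    assert not any(f.startswith("dict[") for f in token_features(toks, [lex])[0])


def test_bi_positioned_dictionary_flags():
    toks = tokenize_sentence("endothelial cells")
    lex = Lexicon.from_surfaces("Cell", ["endothelial cells"])
    feats = token_features(toks, [lex])
    assert "dict[Cell]=B" in feats[0]
    assert "dict[Cell]=I" in feats[1]


# -- training and prediction ---------------------------------------------


def test_training_requires_entities():
    corpus = Corpus(splits={"train": [AnnotatedDocument("d", "no annotation here")]})
    with pytest.raises(ValueError):
        train_ner(corpus)
    with pytest.raises(ValueError):
        train_ner(Corpus(splits={"train": []}))


def test_self_prediction_recovers_training_entities(bench_corpus, ner_base_model):
    """A memorizable training sentence is tagged back correctly."""
    from mlevent.evaluation import evaluate_ner

    train_docs = bench_corpus.splits["train"][:40]
    preds = []
    for d in train_docs:
        pd = AnnotatedDocument(doc_id=d.doc_id, text=d.text)
        for e in predict_entities(ner_base_model, d):
            pd.entities[e.id] = e
        preds.append(pd)
    report = evaluate_ner(train_docs, preds, "exact")
    assert report.overall.f_score > 90.0


def test_prediction_deterministic(bench_corpus, ner_base_model):
    doc = bench_corpus.splits["test"][0]
    a = predict_entities(ner_base_model, doc)
    b = predict_entities(ner_base_model, doc)
    assert a == b


def test_empty_document_predicts_nothing(ner_base_model):
    assert predict_entities(ner_base_model, "") == []


def test_predictions_round_trip_through_standoff(bench_corpus, ner_base_model):
    doc = bench_corpus.splits["test"][1]
    pd = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
    for e in predict_entities(ner_base_model, doc):
        pd.entities[e.id] = e
    a1, a2 = write_standoff(pd)
    from mlevent.standoff import parse_standoff

    assert parse_standoff(pd.text, a1, a2).annotations_equal(pd)
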