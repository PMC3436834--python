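"""Shared fixtures: hand-built documents and the pinned benchmark corpus.

The benchmark corpus (200 documents, seed 7) and the models trained on it
are session-scoped so the learnability checks share one training run.
"""

from __future__ import annotations

import logging

import pytest

from mlevent.model import (
    AnnotatedDocument,
    EntityMention,
    EventArgument,
    EventModification,
    EventStructure,
    EventTrigger,
    TextSpan,
)
from mlevent.ner import train_ner
from mlevent.pipeline import train_pipeline
from mlevent.synth import GeneratorConfig, generate_corpus, generate_lexicons

logging.getLogger("mlevent").setLevel(logging.WARNING)

BENCH_SEED = 7
BENCH_DOCS = 200


class DocBuilder:
    """Minimal hand-construction helper for evaluation fixtures."""

    def __init__(self, text: str, doc_id: str = "doc"):
        self.doc = AnnotatedDocument(doc_id=doc_id, text=text)

    def entity(self, eid, etype, start, end):
        self.doc.entities[eid] = EntityMention(
            eid, etype, TextSpan(start, end), self.doc.text[start:end]
        )
        return self

    def trigger(self, tid, etype, start, end):
        self.doc.triggers[tid] = EventTrigger(
            tid, etype, TextSpan(start, end), self.doc.text[start:end]
        )
        return self

    def event(self, eid, etype, trigger, *args):
        self.doc.events[eid] = EventStructure(
            eid, etype, trigger, tuple(EventArgument(r, t) for r, t in args)
        )
        return self

    def modify(self, mid, kind, target):
        self.doc.modifications[mid] = EventModification(mid, kind, target)
        return self


@pytest.fixture()
def build():
    return DocBuilder


@pytest.fixture(scope="session")
def bench_config():
    return GeneratorConfig(seed=BENCH_SEED, n_documents=BENCH_DOCS)


@pytest.fixture(scope="session")
def bench_corpus(bench_config):
    return generate_corpus(bench_config)


@pytest.fixture(scope="session")
def bench_lexicons(bench_config, bench_corpus):
    return generate_lexicons(bench_config, bench_corpus)


@pytest.fixture(scope="session")
def ner_base_model(bench_corpus):
    return train_ner(bench_corpus, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def ner_dict_model(bench_corpus, bench_lexicons):
    return train_ner(
        bench_corpus, lexicons=list(bench_lexicons.values()), seed=BENCH_SEED
    )


@pytest.fixture(scope="session")
def event_model(bench_corpus):
    return train_pipeline(bench_corpus, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(seed=5, n_documents=30))
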