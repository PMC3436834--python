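"""Evaluation protocols for entity mention detection and event extraction.

Entity mentions are scored under three matching criteria — exact span,
left boundary, right boundary — always requiring identical types.  Events
are scored by recursive structure comparison with two optional relaxations:

* *approximate span*: a predicted trigger span counts as matching when it
  lies within the gold span extended by one word on each side;
* *approximate recursive*: event-valued arguments are compared only on
  their core structure (type, trigger, Theme arguments, recursively),
  ignoring secondary arguments of sub-events.

All scores are micro-averaged: true-positive / false-positive /
false-negative counts are summed over all documents before precision,
recall and F are computed.  Within a document, gold and predicted
annotations are paired by maximum one-to-one bipartite matching, so counts
do not depend on iteration order.  Because a match always requires equal
types, the matching problem decomposes by type and per-category counts sum
exactly to the overall counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx

from .model import AnnotatedDocument, Corpus, EntityMention, EventStructure, TextSpan
from .schema import TaskSchema, default_schema
from .tokenize import segment

__all__ = [
    "EvalCounts",
    "PRF",
    "EventCriteria",
    "EvalReport",
    "f_score",
    "prf_from_counts",
    "match_entity",
    "match_event",
    "evaluate_ner",
    "evaluate_events",
    "corpus_stats",
    "cross_level_fraction",
]

NER_CRITERIA = ("exact", "left", "right")


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "EvalCounts") -> "EvalCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_score: float


@dataclass(frozen=True)
class EventCriteria:
    """Primary task criteria switch both relaxations on (the default)."""

    approximate_span: bool = True
    approximate_recursive: bool = True


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall, on the percentage scale."""
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def prf_from_counts(c: EvalCounts) -> PRF:
    p = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return PRF(p, r, f_score(p, r))


@dataclass
class EvalReport:
    """Overall and per-category micro-averaged scores.

    ``rows`` partition the overall counts by category; ``extra`` rows (the
    event report's Modification row) live in a separate instance space and
    are not part of that partition.
    """

    overall_counts: EvalCounts
    rows: dict[str, EvalCounts] = field(default_factory=dict)
    extra: dict[str, EvalCounts] = field(default_factory=dict)
    footnotes: list[str] = field(default_factory=list)

    @property
    def overall(self) -> PRF:
        return prf_from_counts(self.overall_counts)

    def prf(self, category: str) -> PRF:
        if category in self.rows:
            return prf_from_counts(self.rows[category])
        return prf_from_counts(self.extra[category])

    def to_rows(self) -> list[tuple[str, int, int, int, float, float, float]]:
        out = []
        for name, c in [("overall", self.overall_counts), *self.rows.items(), *self.extra.items()]:
            prf = prf_from_counts(c)
            out.append((name, c.tp, c.fp, c.fn, prf.precision, prf.recall, prf.f_score))
        return out


# -- entity matching -----------------------------------------------------


def match_entity(pred: EntityMention, gold: EntityMention, criterion: str) -> bool:
    if pred.entity_type != gold.entity_type:
        return False
    if criterion == "exact":
        return pred.span == gold.span
    if criterion == "left":
        return pred.span.start == gold.span.start
    if criterion == "right":
        return pred.span.end == gold.span.end
    raise ValueError(f"unknown criterion {criterion!r}")


def _maximum_matching_count(pred_items, gold_items, edge) -> int:
    """Size of a maximum one-to-one matching between the two sides."""
    g = nx.Graph()
    p_nodes = [("p", i) for i in range(len(pred_items))]
    g_nodes = [("g", j) for j in range(len(gold_items))]
    g.add_nodes_from(p_nodes, bipartite=0)
    g.add_nodes_from(g_nodes, bipartite=1)
    for i, p in enumerate(pred_items):
        for j, q in enumerate(gold_items):
            if edge(p, q):
                g.add_edge(("p", i), ("g", j))
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=p_nodes)
    return sum(1 for k in matching if k[0] == "p")


def _matched_pairs(pred_items, gold_items, edge):
    """Maximum matching returned as index pairs."""
    g = nx.Graph()
    p_nodes = [("p", i) for i in range(len(pred_items))]
    g.add_nodes_from(p_nodes, bipartite=0)
    g.add_nodes_from((("g", j) for j in range(len(gold_items))), bipartite=1)
    for i, p in enumerate(pred_items):
        for j, q in enumerate(gold_items):
            if edge(p, q):
                g.add_edge(("p", i), ("g", j))
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=p_nodes)
    return [(k[1], v[1]) for k, v in matching.items() if k[0] == "p"]


def _align(gold_docs, pred_docs) -> list[tuple[AnnotatedDocument, AnnotatedDocument]]:
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(gold_by_id) != set(pred_by_id):
        missing = set(gold_by_id) ^ set(pred_by_id)
        raise ValueError(f"gold/predicted document ids differ: {sorted(missing)[:5]}")
    return [(gold_by_id[i], pred_by_id[i]) for i in sorted(gold_by_id)]


def evaluate_ner(
    gold_docs,
    pred_docs,
    criterion: str = "exact",
    schema: TaskSchema | None = None,
) -> EvalReport:
    """Score predicted entity mentions against gold, micro-averaged.

    Reports overall counts and one row per entity category
    (Organism / Anatomy / Molecule for the MLEE schema).
    """
    if criterion not in NER_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    schema = schema or default_schema()
    report = EvalReport(EvalCounts())
    for cat in schema.entity_categories:
        report.rows[cat] = EvalCounts()

    for gold_doc, pred_doc in _align(gold_docs, pred_docs):
        # equal types are required, so match independently per type
        types = {e.entity_type for e in gold_doc.entities.values()} | {
            e.entity_type for e in pred_doc.entities.values()
        }
        for etype in sorted(types):
            preds = [e for e in pred_doc.entities.values() if e.entity_type == etype]
            golds = [e for e in gold_doc.entities.values() if e.entity_type == etype]
            tp = _maximum_matching_count(
                preds, golds, lambda p, q: match_entity(p, q, criterion)
            )
            c = EvalCounts(tp, len(preds) - tp, len(golds) - tp)
            cat = schema.entity_category(etype)
            report.rows[cat] += c
            report.overall_counts += c
    return report


# -- event matching ------------------------------------------------------


def _extend_one_word(span: TextSpan, text: str) -> TextSpan:
    """Extend a span one whitespace-delimited word left and right."""
    start = span.start
    while start > 0 and text[start - 1].isspace():
        start -= 1
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    end = span.end
    n = len(text)
    while end < n and text[end].isspace():
        end += 1
    while end < n and not text[end].isspace():
        end += 1
    return TextSpan(start, end) if start < end else span


def match_event(
    pred: EventStructure,
    gold: EventStructure,
    pred_doc: AnnotatedDocument,
    gold_doc: AnnotatedDocument,
    criteria: EventCriteria = EventCriteria(),
    _core_only: bool = False,
) -> bool:
    """Recursive structural event comparison.

    ``_core_only`` marks that we are below an event-valued argument under
    the approximate-recursive relaxation: only type, trigger and Theme
    arguments are compared from here down.
    """
    if pred.event_type != gold.event_type:
        return False
    try:
        pt = pred_doc.triggers[pred.trigger]
        gt = gold_doc.triggers[gold.trigger]
    except KeyError as exc:  # dangling reference
        raise ValueError(f"dangling trigger reference: {exc}") from exc
    if criteria.approximate_span:
        if not _extend_one_word(gt.span, gold_doc.text).contains(pt.span):
            return False
    elif pt.span != gt.span:
        return False

    def arg_groups(event: EventStructure) -> dict[str, list]:
        groups: dict[str, list] = {}
        for a in event.arguments:
            base = a.base_role
            if _core_only and base != "Theme":
                continue
            groups.setdefault(base, []).append(a)
        return groups

    pgroups, ggroups = arg_groups(pred), arg_groups(gold)
    if set(pgroups) != set(ggroups):
        return False

    def arg_match(parg, garg) -> bool:
        if parg.is_event_ref != garg.is_event_ref:
            return False
        if parg.is_event_ref:
            try:
                sub_p = pred_doc.events[parg.target]
                sub_g = gold_doc.events[garg.target]
            except KeyError as exc:
                raise ValueError(f"dangling event reference: {exc}") from exc
            return match_event(
                sub_p,
                sub_g,
                pred_doc,
                gold_doc,
                criteria,
                _core_only=_core_only or criteria.approximate_recursive,
            )
        try:
            pe = pred_doc.entities[parg.target]
            ge = gold_doc.entities[garg.target]
        except KeyError as exc:
            raise ValueError(f"dangling entity reference: {exc}") from exc
        return pe.entity_type == ge.entity_type and pe.span == ge.span

    for base in pgroups:
        pargs, gargs = pgroups[base], ggroups[base]
        if len(pargs) != len(gargs):
            return False
        # within a role, repeated arguments pair order-insensitively;
        # groups are tiny, so try all bijections
        if not any(
            all(arg_match(pa, ga) for pa, ga in zip(pargs, perm))
            for perm in permutations(gargs)
        ):
            return False
    return True


def evaluate_events(
    gold_docs,
    pred_docs,
    criteria: EventCriteria = EventCriteria(),
    schema: TaskSchema | None = None,
) -> EvalReport:
    """Score predicted events against gold, micro-averaged.

    Rows cover the event categories (Anatomical / Molecular / General /
    Planned for the MLEE schema) plus a Modification row scoring Negation
    and Speculation flags: a predicted modification is a true positive iff
    its event matched a gold event carrying the same flag; modifications on
    unmatched events count as false positives.
    """
    schema = schema or default_schema()
    report = EvalReport(EvalCounts())
    for cat in schema.event_categories:
        report.rows[cat] = EvalCounts()
    mod_counts = EvalCounts()

    for gold_doc, pred_doc in _align(gold_docs, pred_docs):
        types = {e.event_type for e in gold_doc.events.values()} | {
            e.event_type for e in pred_doc.events.values()
        }
        matched_gold: dict[str, str] = {}  # pred event id -> gold event id
        for etype in sorted(types):
            preds = [e for e in pred_doc.events.values() if e.event_type == etype]
            golds = [e for e in gold_doc.events.values() if e.event_type == etype]
            pairs = _matched_pairs(
                preds,
                golds,
                lambda p, q: match_event(p, q, pred_doc, gold_doc, criteria),
            )
            tp = len(pairs)
            c = EvalCounts(tp, len(preds) - tp, len(golds) - tp)
            report.rows[schema.event_category(etype)] += c
            report.overall_counts += c
            for pi, gi in pairs:
                matched_gold[preds[pi].id] = golds[gi].id

        gold_tp_flags: set[tuple[str, str]] = set()
        for mod in pred_doc.modifications.values():
            gid = matched_gold.get(mod.target)
            if gid is not None and mod.kind in gold_doc.modification_flags(gid):
                mod_counts.tp += 1
                gold_tp_flags.add((gid, mod.kind))
            else:
                mod_counts.fp += 1
        for mod in gold_doc.modifications.values():
            if (mod.target, mod.kind) not in gold_tp_flags:
                mod_counts.fn += 1

    report.extra["Modification"] = mod_counts
    report.footnotes.append(
        "Modification row: predicted flags on unmatched events count as "
        "false positives."
    )
    return report


# -- corpus statistics ---------------------------------------------------


def corpus_stats(corpus: Corpus, schema: TaskSchema | None = None) -> dict:
    """Per-split counts of documents, sentences, words, entities and events
    by category, and modifications, plus a summed ``total`` column.

    Words are whitespace-delimited tokens; sentences come from the
    package's sentence splitter.
    """
    schema = schema or default_schema()
    ecats = schema.entity_categories
    vcats = schema.event_categories

    def new_row() -> dict:
        row = {"documents": 0, "sentences": 0, "words": 0, "entities": 0}
        row["entities_by_category"] = {c: 0 for c in ecats}
        row["events"] = 0
        row["events_by_category"] = {c: 0 for c in vcats}
        row["modifications"] = 0
        return row

    stats = {}
    total = new_row()
    for split in Corpus.SPLIT_NAMES:
        row = new_row()
        for doc in corpus.splits.get(split, []):
            row["documents"] += 1
            row["sentences"] += len(segment(doc.text))
            row["words"] += len(doc.text.split())
            row["entities"] += len(doc.entities)
            for ent in doc.entities.values():
                row["entities_by_category"][schema.entity_category(ent.entity_type)] += 1
            row["events"] += len(doc.events)
            for ev in doc.events.values():
                row["events_by_category"][schema.event_category(ev.event_type)] += 1
            row["modifications"] += len(doc.modifications)
        stats[split] = row
        for key in ("documents", "sentences", "words", "entities", "events", "modifications"):
            total[key] += row[key]
        for c in ecats:
            total["entities_by_category"][c] += row["entities_by_category"][c]
        for c in vcats:
            total["events_by_category"][c] += row["events_by_category"][c]
    stats["total"] = total
    return stats


# -- cross-level events --------------------------------------------------


def _closure_categories(
    doc: AnnotatedDocument, schema: TaskSchema, cache: dict[str, frozenset[str]], event_id: str,
    _stack: frozenset[str] = frozenset(),
) -> frozenset[str]:
    if event_id in cache:
        return cache[event_id]
    if event_id in _stack:
        raise ValueError(f"cycle through event {event_id}")
    cats: set[str] = set()
    ev = doc.events[event_id]
    for arg in ev.arguments:
        if arg.is_event_ref:
            cats |= _closure_categories(
                doc, schema, cache, arg.target, _stack | {event_id}
            )
        else:
            cats.add(schema.entity_category(doc.entities[arg.target].entity_type))
    result = frozenset(cats)
    cache[event_id] = result
    return result


def cross_level_fraction(
    source: Corpus | list[AnnotatedDocument], schema: TaskSchema | None = None
) -> float:
    """Fraction of events whose transitive argument closure reaches both the
    molecular level and the organism/anatomy level.

    The closure of an event is the set of entity categories reachable by
    following its arguments, descending through event-valued arguments.  An
    event counts as cross-level when the closure contains Molecule and at
    least one of Organism / Anatomy.  Returns 0.0 for an event-free corpus.
    """
    schema = schema or default_schema()
    docs = source.documents() if isinstance(source, Corpus) else source
    crossing = total = 0
    for doc in docs:
        cache: dict[str, frozenset[str]] = {}
        for eid in doc.events:
            cats = _closure_categories(doc, schema, cache, eid)
            total += 1
            if "Molecule" in cats and ({"Organism", "Anatomy"} & cats):
                crossing += 1
    return crossing / total if total else 0.0
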