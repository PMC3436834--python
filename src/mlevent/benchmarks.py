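"""Published MLEE corpus statistics and benchmark results, as data.

These are the reference numbers distributed with the MLEE resource:
the corpus summary table, entity mention detection results (overall and by
category for the dictionary model) and event extraction results (overall
and by category for the stacked model).  They serve as worked examples for
the metric arithmetic — every printed F score must be recoverable from its
printed precision/recall pair — and as distributional targets for the
synthetic corpus generator.

Precision/recall/F values are percentages as printed (2 d.p.).
"""

from __future__ import annotations

__all__ = [
    "MLEE_CORPUS_STATS",
    "MLEE_ENTITY_TYPE_COUNTS",
    "MLEE_EVENT_TYPE_COUNTS",
    "NER_OVERALL_RESULTS",
    "NER_CATEGORY_RESULTS",
    "EVENT_OVERALL_RESULTS",
    "EVENT_CATEGORY_RESULTS",
    "CROSS_LEVEL_EVENT_COUNT",
    "fixture_tables",
]

#: Corpus summary: item -> (train, devel, test, total).
MLEE_CORPUS_STATS: dict[str, tuple[int, int, int, int]] = {
    "Document": (131, 44, 87, 262),
    "Sentence": (1271, 457, 880, 2608),
    "Word": (27875, 9610, 19103, 56588),
    "Entity": (4147, 1431, 2713, 8291),
    "Organism": (359, 126, 237, 722),
    "Anatomy": (1844, 589, 1166, 3599),
    "Molecule": (1944, 716, 1310, 3970),
    "Event": (3296, 1175, 2206, 6677),
    "Anatomical": (810, 269, 596, 1675),
    "Molecular": (340, 125, 240, 705),
    "General": (1851, 627, 1176, 3654),
    "Planned": (295, 154, 194, 643),
}

#: Events reaching both the molecular and the organism/anatomy level.
CROSS_LEVEL_EVENT_COUNT = 1222

#: Whole-corpus annotation counts per entity type.
MLEE_ENTITY_TYPE_COUNTS: dict[str, int] = {
    "Organism": 722,
    "Organism subdivision": 49,
    "Anatomical system": 18,
    "Organ": 176,
    "Multi-tissue structure": 514,
    "Tissue": 426,
    "Cell": 1198,
    "Cellular component": 145,
    "Developing anatomical structure": 6,
    "Organism substance": 142,
    "Immaterial anatomical entity": 15,
    "Pathological formation": 910,
    "Drug or compound": 944,
    "Gene or gene product": 2962,
}

#: Whole-corpus annotation counts per event type.
MLEE_EVENT_TYPE_COUNTS: dict[str, int] = {
    "Cell proliferation": 133,
    "Development": 316,
    "Blood vessel development": 855,
    "Growth": 169,
    "Death": 97,
    "Breakdown": 69,
    "Remodeling": 33,
    "Synthesis": 17,
    "Gene expression": 435,
    "Transcription": 37,
    "Catabolism": 26,
    "Phosphorylation": 33,
    "Dephosphorylation": 6,
    "Localization": 450,
    "Binding": 184,
    "Regulation": 773,
    "Positive regulation": 1327,
    "Negative regulation": 921,
    "Planned process": 643,
}

#: model -> criterion -> (precision, recall, f) as printed.
NER_OVERALL_RESULTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "base": {
        "exact": (77.03, 69.18, 72.89),
        "left": (79.85, 71.72, 75.57),
        "right": (82.47, 74.07, 78.04),
    },
    "dictionary": {
        "exact": (79.49, 73.77, 76.52),
        "left": (82.59, 76.64, 79.50),
        "right": (84.68, 78.58, 81.52),
    },
}

#: dictionary model, category -> criterion -> (precision, recall, f).
NER_CATEGORY_RESULTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "Organism": {
        "exact": (90.82, 82.10, 86.24),
        "left": (91.79, 82.97, 87.16),
        "right": (91.79, 82.97, 87.16),
    },
    "Anatomy": {
        "exact": (77.47, 72.70, 75.01),
        "left": (78.67, 73.83, 76.17),
        "right": (84.58, 79.38, 81.90),
    },
    "Molecule": {
        "exact": (79.37, 73.25, 76.18),
        "left": (84.54, 78.03, 81.15),
        "right": (83.54, 77.10, 80.19),
    },
}

#: model -> (precision, recall, f), primary task criteria.
EVENT_OVERALL_RESULTS: dict[str, tuple[float, float, float]] = {
    "base": (56.53, 48.72, 52.34),
    "stacking": (56.38, 50.77, 53.43),
}

#: stacked model, category -> (precision, recall, f).
EVENT_CATEGORY_RESULTS: dict[str, tuple[float, float, float]] = {
    "Anatomical": (80.91, 72.05, 76.22),
    "Molecular": (68.44, 75.63, 71.86),
    "General": (43.87, 38.99, 41.29),
    "Planned": (56.68, 51.96, 54.22),
    "Modification": (47.95, 29.92, 36.85),
}


def fixture_tables() -> dict:
    """All reference tables bundled for worked-example tests."""
    return {
        "corpus_stats": MLEE_CORPUS_STATS,
        "entity_type_counts": MLEE_ENTITY_TYPE_COUNTS,
        "event_type_counts": MLEE_EVENT_TYPE_COUNTS,
        "ner_overall": NER_OVERALL_RESULTS,
        "ner_by_category": NER_CATEGORY_RESULTS,
        "event_overall": EVENT_OVERALL_RESULTS,
        "event_by_category": EVENT_CATEGORY_RESULTS,
        "cross_level_event_count": CROSS_LEVEL_EVENT_COUNT,
    }


def all_prf_rows() -> list[tuple[str, float, float, float]]:
    """Flatten every published (P, R, F) triple with a row label."""
    rows: list[tuple[str, float, float, float]] = []
    for model, crits in NER_OVERALL_RESULTS.items():
        for crit, (p, r, f) in crits.items():
            rows.append((f"ner/{model}/{crit}", p, r, f))
    for cat, crits in NER_CATEGORY_RESULTS.items():
        for crit, (p, r, f) in crits.items():
            rows.append((f"ner-category/{cat}/{crit}", p, r, f))
    for model, (p, r, f) in EVENT_OVERALL_RESULTS.items():
        rows.append((f"event/{model}", p, r, f))
    for cat, (p, r, f) in EVENT_CATEGORY_RESULTS.items():
        rows.append((f"event-category/{cat}", p, r, f))
    return rows
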