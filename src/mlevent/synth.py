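"""Seeded generator of synthetic annotated abstracts.

Documents are built sentence by sentence from templated clauses over a
small biomedical surface vocabulary, with gold standoff annotation
(entities, triggers, events, modifications) constructed alongside the
text, so every other module is trainable and testable without any
external corpus.

Distributional targets
----------------------

* Entity and event type frequencies default to the published MLEE
  annotation counts; the marginal type of every generated event is drawn
  so realized proportions converge to these weights.
* Events nest through Regulation-family Themes; nesting depth is
  geometric (continue probability ``nesting_p``, maximum depth 3).
* A configurable fraction of events (default 0.18) is *cross-level*:
  its argument closure reaches both the molecular and the
  organism/anatomy level.  Cross-level events are generated as dedicated
  single-event units (a General or Planned type combining a molecular
  with an anatomical participant) while all other units keep their
  entities on one level, so the realized per-event fraction is controlled
  exactly.  The per-unit probability of emitting a cross-level unit and
  the compensating reweighting of non-cross event types are derived
  analytically from the configuration (see the package methods note).
* Negation / Speculation are realized with sentence-level cue words
  ("did not", "No ... was observed", "may") on the top event of a unit.

Every generated document round-trips through the standoff serializer and
passes structural and schema validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .benchmarks import (
    MLEE_CORPUS_STATS,
    MLEE_ENTITY_TYPE_COUNTS,
    MLEE_EVENT_TYPE_COUNTS,
    fixture_tables,
)
from .model import (
    AnnotatedDocument,
    Corpus,
    EntityMention,
    EventArgument,
    EventModification,
    EventStructure,
    EventTrigger,
    TextSpan,
)
from .ner import Lexicon
from .schema import TaskSchema, default_schema

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "generate_lexicons",
    "fixture_tables",
]


# -- surface vocabulary --------------------------------------------------

ENTITY_VOCAB: dict[str, tuple[str, ...]] = {
    "Organism": ("human", "mice", "C. albicans", "patients", "rats", "zebrafish", "rabbits"),
    "Organism subdivision": ("head", "thorax", "hindlimb", "legs", "trunk"),
    "Anatomical system": ("central nervous system", "pulmonary system", "immune system", "vasculature"),
    "Organ": ("heart", "eyes", "skin", "liver", "kidney", "lung", "cornea"),
    "Multi-tissue structure": (
        "blood vessel", "peritoneal membrane", "lymph nodes", "retina",
        "capillary wall", "aorta", "microvessels",
    ),
    "Tissue": ("endothelium", "adipose tissue", "granulation tissue", "epithelium", "myocardium"),
    "Cell": (
        "endothelial cells", "HUVECs", "pericytes", "cancer cells", "macrophages",
        "fibroblasts", "monocytes", "smooth muscle cells", "tumor cells", "mast cells",
    ),
    "Cellular component": (
        "nuclei", "focal adhesions", "extracellular matrix", "cytoplasm", "mitochondria",
    ),
    "Developing anatomical structure": ("embryo", "embryos", "limb bud"),
    "Organism substance": ("blood", "serum", "plasma", "urine"),
    "Immaterial anatomical entity": ("lumen", "preperitoneal space", "marrow cavity"),
    "Pathological formation": (
        "tumor", "colorectal cancer", "gliomas", "tumours", "melanoma",
        "carcinoma", "metastases", "wounds",
    ),
    "Drug or compound": (
        "oxygen", "ethanol", "bevacizumab", "thalidomide", "nitric oxide",
        "cisplatin", "paclitaxel", "rapamycin", "heparin", "celecoxib",
    ),
    "Gene or gene product": (
        "VEGF", "p53", "IL-8", "endostatin", "thrombin", "VEGFR-2", "bFGF",
        "TNF-alpha", "angiostatin", "MMP-9", "MMP-2", "EGFR", "KDR",
        "HIF-1alpha", "eNOS", "PDGF", "IL-6", "TGF-beta",
    ),
}

#: Noun-form trigger surfaces per event type.
TRIGGER_NOUNS: dict[str, tuple[str, ...]] = {
    "Cell proliferation": ("proliferation", "expansion"),
    "Development": ("development", "formation", "maturation"),
    "Blood vessel development": ("angiogenesis", "neovascularization", "vascularization", "revascularization"),
    "Growth": ("growth", "enlargement", "outgrowth"),
    "Death": ("necrosis", "apoptosis", "death"),
    "Breakdown": ("damage", "disruption", "rupture", "degradation"),
    "Remodeling": ("remodeling", "reorganization"),
    "Synthesis": ("synthesis", "production", "biosynthesis"),
    "Gene expression": ("expression", "overexpression"),
    "Transcription": ("transcription",),
    "Catabolism": ("catabolism", "proteolysis", "turnover"),
    "Phosphorylation": ("phosphorylation", "autophosphorylation"),
    "Dephosphorylation": ("dephosphorylation",),
    "Localization": ("localization", "secretion", "migration", "translocation"),
    "Binding": ("binding", "adhesion", "attachment"),
    "Regulation": ("regulation", "modulation", "control"),
    "Positive regulation": ("induction", "stimulation", "activation", "upregulation"),
    "Negative regulation": ("inhibition", "suppression", "reduction", "downregulation"),
    "Planned process": ("injection", "administration", "treatment", "transplantation"),
}

#: (third person, infinitive) verb triggers for Regulation-family types.
REG_VERBS: dict[str, tuple[tuple[str, str], ...]] = {
    "Regulation": (("modulates", "modulate"), ("affects", "affect"), ("regulates", "regulate")),
    "Positive regulation": (("stimulates", "stimulate"), ("induces", "induce"), ("enhances", "enhance"), ("promotes", "promote")),
    "Negative regulation": (("inhibits", "inhibit"), ("suppresses", "suppress"), ("attenuates", "attenuate"), ("blocks", "block")),
}

_REG_FAMILY = ("Regulation", "Positive regulation", "Negative regulation")

_LEADS = (
    ("We", "observed"),
    ("The", "results", "showed"),
    ("These", "data", "demonstrated"),
    ("Histology", "revealed"),
    ("The", "analysis", "confirmed"),
)

_FILLER_SENTENCES = (
    ("These", "results", "are", "consistent", "with", "previous", "reports"),
    ("The", "underlying", "mechanism", "remains", "poorly", "understood"),
    ("Further", "studies", "are", "required", "to", "confirm", "these", "findings"),
)

#: Types whose mentions also come from open-ended name patterns, so held-out
#: splits contain surface forms never seen in training — the regime in which
#: dictionary features genuinely matter for mention detection.
_VARIANT_TYPES = ("Gene or gene product", "Drug or compound", "Cell")

_DRUG_PREFIXES = ("velu", "dora", "mira", "zeta", "calo", "pexi", "ranu", "solo")
_DRUG_SUFFIXES = ("mab", "nib", "stat", "zole", "cin", "parib")

_DISTRACTOR_TERMS = (
    "flavozyme", "cortexin", "neurolide", "plasmogen", "vasculin",
    "stromafin", "lymphotide", "dermatose", "osteolin", "glycophan",
    "myotropin", "fibrocyclin",
)


# -- configuration -------------------------------------------------------


def _default_split_sizes() -> tuple[int, int, int]:
    return MLEE_CORPUS_STATS["Document"][:3]


@dataclass
class GeneratorConfig:
    """Seeded specification of a synthetic corpus.

    Split proportions, entity-type and event-type weights default to the
    published MLEE corpus figures; rates are probabilities in [0, 1].
    """

    seed: int
    n_documents: int = 60
    split_proportions: tuple[int, int, int] = field(default_factory=_default_split_sizes)
    sentences_per_doc: tuple[int, int] = (8, 12)  # inclusive range
    entity_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(MLEE_ENTITY_TYPE_COUNTS)
    )
    event_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(MLEE_EVENT_TYPE_COUNTS)
    )
    cross_level_rate: float = 0.18
    negation_rate: float = 0.06
    speculation_rate: float = 0.05
    nesting_p: float = 0.5
    max_nesting: int = 3
    standalone_rate: float = 0.15
    bvd_trigger_only_rate: float = 0.5
    cause_rate: float = 0.45
    site_rate: float = 0.15
    atloc_rate: float = 0.4
    second_theme_rate: float = 0.2
    instrument_rate: float = 0.4
    #: probability that a Gene/Drug/Cell mention uses a freshly patterned
    #: name (large combinatorial space, hence mostly unseen across splits)
    novel_surface_rate: float = 0.25
    lexicon_coverage: float = 0.8
    distractors_per_category: int = 8

    def validate(self, schema: TaskSchema) -> None:
        for name, w in {**self.entity_type_weights, **self.event_type_weights}.items():
            if w < 0:
                raise ValueError(f"negative weight for {name}")
        for rate_name in (
            "cross_level_rate", "negation_rate", "speculation_rate", "nesting_p",
            "standalone_rate", "bvd_trigger_only_rate", "lexicon_coverage",
        ):
            v = getattr(self, rate_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{rate_name}={v} outside [0, 1]")
        for name in self.event_type_weights:
            if name not in schema.event_types:
                raise ValueError(f"event type {name!r} not in schema")
            if self.event_type_weights[name] > 0 and name not in TRIGGER_NOUNS:
                raise ValueError(f"template inventory lacks event type {name!r}")
        for name in self.entity_type_weights:
            if name not in schema.entity_types:
                raise ValueError(f"entity type {name!r} not in schema")
            if self.entity_type_weights[name] > 0 and name not in ENTITY_VOCAB:
                raise ValueError(f"template inventory lacks entity type {name!r}")


# -- derived sampling distributions --------------------------------------


class _Plan:
    """Sampling distributions derived analytically from a configuration."""

    def __init__(self, config: GeneratorConfig, schema: TaskSchema):
        self.config = config
        self.schema = schema
        ecat = {t: schema.entity_category(t) for t in config.entity_type_weights}
        vcat = {t: schema.event_category(t) for t in config.event_type_weights}

        w = {t: float(v) for t, v in config.event_type_weights.items() if v > 0}
        total = sum(w.values())
        shared = {t for t in w if vcat[t] in ("General", "Planned")}
        f = config.cross_level_rate

        # cross-level units draw from General/Planned types (the ones whose
        # role inventory can combine molecular with anatomical participants);
        # non-cross weights are reduced so the mixture of cross (fraction f of
        # all events) and non-cross events reproduces the configured weights.
        w_shared = sum(w[t] for t in shared)
        self.cross_types = sorted(shared)
        self.cross_probs = _normalize([w[t] for t in self.cross_types])
        scale = max(0.0, 1.0 - f * total / w_shared) if w_shared else 0.0
        if w_shared and f * total / w_shared > 1.0:
            logger.warning(
                "cross_level_rate %.2f exceeds the General+Planned weight share; "
                "realized type proportions will deviate",
                f,
            )
        noncross = {t: (w[t] * scale if t in shared else w[t]) for t in w}

        # side split: shared types halved on each side so every type's
        # realized marginal stays proportional to its configured weight
        def side_weights(categories: tuple[str, ...]) -> dict[str, float]:
            out = {}
            for t, v in noncross.items():
                if vcat[t] in categories:
                    out[t] = v
                elif t in shared:
                    out[t] = v / 2.0
            return out

        self.a_side = side_weights(("Anatomical",))
        self.m_side = side_weights(("Molecular",))
        wa, wm = sum(self.a_side.values()), sum(self.m_side.values())

        # expected events per non-cross unit on each side:
        # q = P(regulation-family node | side), p = nesting probability,
        # tree size T(depth) = 1 + q p T(depth+1)
        p = config.nesting_p

        def tree_size(side: dict[str, float]) -> float:
            tot = sum(side.values())
            q = sum(side.get(t, 0.0) for t in _REG_FAMILY) / tot if tot else 0.0
            size = 1.0
            for _ in range(config.max_nesting - 1):
                size = 1.0 + q * p * size
            return size

        size_a, size_m = tree_size(self.a_side), tree_size(self.m_side)
        # molecular-side trees nest more (regulation is a larger share of
        # that side's mass), so the side choice is weighted by inverse
        # expected size: expected node counts per side then stay
        # proportional to the side weight masses and the marginal type of
        # every generated event remains proportional to its configured
        # weight
        ra, rm = (wa / size_a if size_a else 0.0), (wm / size_m if size_m else 0.0)
        self.p_side_a = ra / (ra + rm) if ra + rm else 0.5
        size = self.p_side_a * size_a + (1.0 - self.p_side_a) * size_m
        self.expected_unit_size = size
        if f > 0.0 and not self.cross_types:
            logger.warning(
                "cross_level_rate %.2f requested but no General/Planned event "
                "types are configured; generating no cross-level events", f
            )
            f = 0.0
        self.cross_unit_prob = (
            f * size / (1.0 - f + f * size) if 0.0 < f else 0.0
        )

        # entity side pools
        self.anat_entity_types = sorted(
            t for t, v in config.entity_type_weights.items()
            if v > 0 and ecat[t] in ("Anatomy", "Organism")
        )
        self.anat_entity_probs = _normalize(
            [config.entity_type_weights[t] for t in self.anat_entity_types]
        )
        self.mol_entity_types = sorted(
            t for t, v in config.entity_type_weights.items()
            if v > 0 and ecat[t] == "Molecule"
        )
        self.mol_entity_probs = _normalize(
            [config.entity_type_weights[t] for t in self.mol_entity_types]
        )
        self.all_entity_types = sorted(
            t for t, v in config.entity_type_weights.items() if v > 0
        )
        self.all_entity_probs = _normalize(
            [config.entity_type_weights[t] for t in self.all_entity_types]
        )

        self.a_types = sorted(self.a_side)
        self.a_probs = _normalize([self.a_side[t] for t in self.a_types])
        self.m_types = sorted(self.m_side)
        self.m_probs = _normalize([self.m_side[t] for t in self.m_types])


def _normalize(weights: list[float]) -> np.ndarray:
    arr = np.asarray(weights, dtype=float)
    s = arr.sum()
    return arr / s if s else arr


# -- sentence construction ----------------------------------------------


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc = AnnotatedDocument(doc_id=doc_id, text="")
        self._parts: list[str] = []
        self._pos = 0
        self._n_t = 0
        self._n_e = 0
        self._n_m = 0

    def _append(self, token: str) -> TextSpan:
        if self._parts:
            self._parts.append(" ")
            self._pos += 1
        start = self._pos
        self._parts.append(token)
        self._pos += len(token)
        return TextSpan(start, self._pos)

    def words(self, *tokens: str) -> None:
        for tok in tokens:
            self._append(tok)

    def entity(self, entity_type: str, surface: str) -> str:
        span = self._append(surface)
        self._n_t += 1
        eid = f"T{self._n_t}"
        self.doc.entities[eid] = EntityMention(eid, entity_type, span, surface)
        return eid

    def trigger(self, event_type: str, surface: str) -> str:
        span = self._append(surface)
        self._n_t += 1
        tid = f"T{self._n_t}"
        self.doc.triggers[tid] = EventTrigger(tid, event_type, span, surface)
        return tid

    def event(self, event_type: str, trigger_id: str, args) -> str:
        self._n_e += 1
        eid = f"E{self._n_e}"
        self.doc.events[eid] = EventStructure(eid, event_type, trigger_id, tuple(args))
        return eid

    def modify(self, kind: str, event_id: str) -> None:
        self._n_m += 1
        self.doc.modifications[f"M{self._n_m}"] = EventModification(
            f"M{self._n_m}", kind, event_id
        )

    def end_sentence(self) -> None:
        self._parts.append(" .")
        self._pos += 2

    def finish(self) -> AnnotatedDocument:
        self.doc.text = "".join(self._parts) + "\n"
        return self.doc


def _choice(rng: np.random.Generator, items, probs=None):
    idx = int(rng.choice(len(items), p=probs))
    return items[idx]


class _Generator:
    def __init__(self, config: GeneratorConfig, schema: TaskSchema):
        self.config = config
        self.schema = schema
        self.plan = _Plan(config, schema)
        self.rng = np.random.default_rng(config.seed)

    # entity / trigger surface draws -------------------------------------
    def _code_name(self) -> str:
        """Bare alphanumeric code ("QR-7"): the same open name space is used
        by cell lines and gene products, so surface shape alone cannot
        decide the category — the regime where dictionary lookup earns its
        keep."""
        rng = self.rng
        k = 2 + int(rng.integers(0, 2))
        letters = "".join(chr(ord("A") + int(rng.integers(26))) for _ in range(k))
        return f"{letters}-{int(rng.integers(1, 30))}"

    def _novel_surface(self, etype: str) -> str:
        rng = self.rng
        if etype == "Gene or gene product":
            return self._code_name()
        if etype == "Drug or compound":
            return _choice(rng, _DRUG_PREFIXES) + _choice(rng, _DRUG_SUFFIXES)
        # Cell: cell-line codes, sometimes with an explicit head noun
        code = self._code_name()
        return code if rng.random() < 0.5 else f"{code} cells"

    def _entity(self, b: _DocBuilder, side: str, determiner_ok: bool = True) -> str:
        plan = self.plan
        if side == "A":
            etype = _choice(self.rng, plan.anat_entity_types, plan.anat_entity_probs)
        elif side == "M":
            etype = _choice(self.rng, plan.mol_entity_types, plan.mol_entity_probs)
        else:
            etype = _choice(self.rng, plan.all_entity_types, plan.all_entity_probs)
        if etype in _VARIANT_TYPES and self.rng.random() < self.config.novel_surface_rate:
            surface = self._novel_surface(etype)
        else:
            surface = _choice(self.rng, ENTITY_VOCAB[etype])
        cat = self.schema.entity_category(etype)
        if determiner_ok and cat != "Molecule" and self.rng.random() < 0.3:
            b.words("the")
        return b.entity(etype, surface)

    def _noun_trigger(self, b: _DocBuilder, event_type: str) -> str:
        return b.trigger(event_type, _choice(self.rng, TRIGGER_NOUNS[event_type]))

    # units ---------------------------------------------------------------
    def _extras(self, b: _DocBuilder, event_type: str, side: str, args: list) -> None:
        """Optional non-Theme entity arguments, realized as postmodifiers."""
        cfg, rng = self.config, self.rng
        roles = self.schema.allowed_roles(event_type)
        if "Site" in roles and event_type not in _REG_FAMILY and rng.random() < cfg.site_rate:
            b.words("at")
            args.append(EventArgument("Site", self._entity(b, side)))
        if "AtLoc" in roles and side == "A" and rng.random() < cfg.atloc_rate:
            b.words("in")
            args.append(EventArgument("AtLoc", self._entity(b, "A")))
        if (
            "ToLoc" in roles
            and side == "A"
            and rng.random() < cfg.site_rate
        ):
            b.words("to")
            args.append(EventArgument("ToLoc", self._entity(b, "A")))

    def _base_event_np(self, b: _DocBuilder, event_type: str, side: str) -> str:
        """A non-Regulation event as a noun phrase; returns the event id."""
        cfg, rng = self.config, self.rng
        args: list[EventArgument] = []
        if event_type == "Blood vessel development" and rng.random() < cfg.bvd_trigger_only_rate:
            tid = self._noun_trigger(b, event_type)
            if rng.random() < cfg.atloc_rate:
                b.words("in")
                args.append(EventArgument("AtLoc", self._entity(b, "A")))
            return b.event(event_type, tid, args)
        tid = self._noun_trigger(b, event_type)
        b.words("of")
        args.append(EventArgument("Theme", self._entity(b, side)))
        if (
            event_type == "Binding"
            and rng.random() < cfg.second_theme_rate
        ):
            b.words("and")
            args.append(EventArgument("Theme2", self._entity(b, side)))
        if event_type == "Planned process" and side == "M" and rng.random() < cfg.instrument_rate:
            b.words("using")
            args.append(EventArgument("Instrument", self._entity(b, "M")))
        self._extras(b, event_type, side, args)
        return b.event(event_type, tid, args)

    def _draw_type(self, side: str) -> str:
        plan = self.plan
        if side == "A":
            return _choice(self.rng, plan.a_types, plan.a_probs)
        return _choice(self.rng, plan.m_types, plan.m_probs)

    def _event_np(self, b: _DocBuilder, side: str, depth: int) -> str:
        """An event noun phrase, possibly a nested Regulation chain."""
        etype = self._draw_type(side)
        if etype in _REG_FAMILY:
            tid = self._noun_trigger(b, etype)
            b.words("of")
            args: list[EventArgument] = []
            if depth < self.config.max_nesting and self.rng.random() < self.config.nesting_p:
                args.append(EventArgument("Theme", self._event_np(b, side, depth + 1)))
            else:
                args.append(EventArgument("Theme", self._entity(b, side)))
            if self.rng.random() < self.config.cause_rate:
                b.words("by")
                args.append(EventArgument("Cause", self._entity(b, side)))
            return b.event(etype, tid, args)
        return self._base_event_np(b, etype, side)

    def _event_unit(self, b: _DocBuilder) -> None:
        rng, cfg = self.rng, self.config
        side = "A" if rng.random() < self.plan.p_side_a else "M"
        etype = self._draw_type(side)

        neg = rng.random() < cfg.negation_rate
        spec = rng.random() < cfg.speculation_rate

        if etype in _REG_FAMILY and rng.random() < cfg.cause_rate:
            # verb-style: "<Cause> stimulates <Theme>."
            cause = self._entity(b, side)
            third, inf = _choice(rng, REG_VERBS[etype])
            if neg:
                b.words("did", "not")
                tid = b.trigger(etype, inf)
            elif spec:
                b.words("may")
                tid = b.trigger(etype, inf)
            else:
                tid = b.trigger(etype, third)
            args = [EventArgument("Cause", cause)]
            if rng.random() < cfg.nesting_p:
                args.insert(0, EventArgument("Theme", self._event_np(b, side, depth=2)))
            else:
                args.insert(0, EventArgument("Theme", self._entity(b, side)))
            eid = b.event(etype, tid, args)
        else:
            # noun-style: "We observed <event NP>." / "No <event NP> was
            # observed." / "<event NP> may occur."
            if neg:
                b.words("No")
            elif not spec:
                b.words(*_choice(rng, _LEADS))
            if etype in _REG_FAMILY:
                tid = self._noun_trigger(b, etype)
                b.words("of")
                args = []
                if rng.random() < cfg.nesting_p:
                    args.append(EventArgument("Theme", self._event_np(b, side, depth=2)))
                else:
                    args.append(EventArgument("Theme", self._entity(b, side)))
                eid = b.event(etype, tid, args)
            else:
                eid = self._base_event_np(b, etype, side)
            if neg:
                b.words("was", "observed")
            elif spec:
                b.words("may", "occur")
        if neg:
            b.modify("Negation", eid)
        if spec:
            b.modify("Speculation", eid)
        b.end_sentence()

    def _cross_unit(self, b: _DocBuilder) -> None:
        """A single event whose closure spans both levels."""
        rng, cfg = self.rng, self.config
        etype = _choice(rng, self.plan.cross_types, self.plan.cross_probs)
        if etype in _REG_FAMILY:
            # "Inhibition of <Anatomy> by <Molecule> was observed."
            b.words(*_choice(rng, _LEADS))
            tid = self._noun_trigger(b, etype)
            b.words("of")
            theme = self._entity(b, "A")
            b.words("by")
            cause = self._entity(b, "M")
            b.event(etype, tid, [EventArgument("Theme", theme), EventArgument("Cause", cause)])
        elif etype == "Localization":
            b.words(*_choice(rng, _LEADS))
            tid = self._noun_trigger(b, etype)
            b.words("of")
            theme = self._entity(b, "M")
            b.words("in")
            atloc = self._entity(b, "A")
            b.event(etype, tid, [EventArgument("Theme", theme), EventArgument("AtLoc", atloc)])
        elif etype == "Binding":
            b.words(*_choice(rng, _LEADS))
            tid = self._noun_trigger(b, etype)
            b.words("of")
            t1 = self._entity(b, "M")
            b.words("and")
            t2 = self._entity(b, "A")
            b.event(etype, tid, [EventArgument("Theme", t1), EventArgument("Theme2", t2)])
        elif etype == "Planned process":
            b.words(*_choice(rng, _LEADS))
            tid = self._noun_trigger(b, etype)
            b.words("of")
            theme = self._entity(b, "A")
            b.words("using")
            instr = self._entity(b, "M")
            b.event(etype, tid, [EventArgument("Theme", theme), EventArgument("Instrument", instr)])
        else:
            # any other shared type: cross through a repeated Theme
            b.words(*_choice(rng, _LEADS))
            tid = self._noun_trigger(b, etype)
            b.words("of")
            t1 = self._entity(b, "M")
            b.words("and")
            t2 = self._entity(b, "A")
            b.event(etype, tid, [EventArgument("Theme", t1), EventArgument("Theme2", t2)])
        b.end_sentence()

    def _standalone_unit(self, b: _DocBuilder) -> None:
        rng = self.rng
        u = rng.random()
        if u < 0.25:
            b.words(*_choice(rng, _FILLER_SENTENCES))
        elif u < 0.6:
            b.words("The", "role", "of")
            self._entity(b, "any", determiner_ok=False)
            b.words("in")
            self._entity(b, "any")
            b.words("was", "investigated")
        else:
            self._entity(b, "any", determiner_ok=False)
            b.words("was", "analysed", "in")
            self._entity(b, "any")
        b.end_sentence()

    def document(self, doc_id: str) -> AnnotatedDocument:
        rng, cfg = self.rng, self.config
        b = _DocBuilder(doc_id)
        lo, hi = cfg.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        for _ in range(n_sent):
            if rng.random() < cfg.standalone_rate:
                self._standalone_unit(b)
            elif rng.random() < self.plan.cross_unit_prob:
                self._cross_unit(b)
            else:
                self._event_unit(b)
        return b.finish()


def _split_counts(n_documents: int, proportions: tuple[int, int, int]) -> dict[str, int]:
    total = sum(proportions)
    raw = [n_documents * p / total for p in proportions]
    counts = [int(x) for x in raw]
    # largest remainder
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[: n_documents - sum(counts)]:
        counts[i] += 1
    return dict(zip(Corpus.SPLIT_NAMES, counts))


def generate_corpus(
    config: GeneratorConfig, schema: TaskSchema | None = None
) -> Corpus:
    """Generate a synthetic corpus; deterministic given the configuration."""
    schema = schema or default_schema()
    config.validate(schema)
    gen = _Generator(config, schema)
    corpus = Corpus()
    for split, n in _split_counts(config.n_documents, config.split_proportions).items():
        corpus.splits[split] = [
            gen.document(f"{split}-{i:04d}") for i in range(n)
        ]
    n_events = sum(len(d.events) for d in corpus.documents())
    logger.info(
        "generated %d documents, %d events (expected cross-level fraction %.3f)",
        len(corpus),
        n_events,
        config.cross_level_rate,
    )
    return corpus


def generate_lexicons(
    config: GeneratorConfig, corpus: Corpus
) -> dict[str, Lexicon]:
    """Per-entity-category lexicons covering a configurable fraction of the
    corpus surface vocabulary, plus distractor entries.

    Stands in for dictionaries compiled from external terminologies; the
    random subset is drawn deterministically from the generator seed.
    """
    schema = default_schema()
    rng = np.random.default_rng(config.seed + 1)
    by_cat: dict[str, set[str]] = {}
    for doc in corpus.documents():
        for ent in doc.entities.values():
            cat = schema.entity_category(ent.entity_type)
            by_cat.setdefault(cat, set()).add(ent.surface)
    lexicons: dict[str, Lexicon] = {}
    for cat in sorted(by_cat):
        vocab = sorted(by_cat[cat])
        k = int(round(config.lexicon_coverage * len(vocab)))
        chosen = (
            [vocab[i] for i in sorted(rng.choice(len(vocab), size=k, replace=False))]
            if k
            else []
        )
        n_d = config.distractors_per_category
        distractors = [
            f"{_DISTRACTOR_TERMS[int(rng.integers(len(_DISTRACTOR_TERMS)))]}-{int(rng.integers(1, 20))}"
            for _ in range(n_d)
        ]
        lexicons[cat] = Lexicon.from_surfaces(cat, chosen + distractors)
    return lexicons
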