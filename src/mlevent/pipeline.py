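"""Four-stage event extraction pipeline.

Given a document with entity annotations (gold or predicted), events are
extracted in fixed stage order:

1. *trigger detection* — every content-word token is scored against all event
   types (multi-label, one-versus-rest linear classifiers); positive
   margins become typed triggers;
2. *argument detection* — trigger/target pairs within a sentence (targets
   are entities or other triggers) are scored over the argument roles the
   schema allows for the trigger's type;
3. *event assembly* — role-consistent combinations of a trigger's accepted
   argument candidates (including the empty combination, for trigger-only
   events) are enumerated and classified; accepted combinations become
   events, with event-valued arguments resolved bottom-up so sub-events
   exist before the events that reference them;
4. *modification detection* — assembled events are flagged for Negation
   and Speculation.

Semantic class generalization maps fine event types onto coarse classes
(the three Regulation types merge; the six single-Theme anatomical process
types merge) and feature templates are emitted both per-type and
per-class, which shares statistics across sparse types.

Stacking: a source pipeline model's predictions on the same text can be
injected as extra features at stages 1 and 2, after mapping the source's
event types onto this schema's types.

All stage classifiers are linear one-versus-rest SVMs with a margin
threshold of 0; a candidate with no positive margin is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .model import (
    AnnotatedDocument,
    Corpus,
    EventArgument,
    EventModification,
    EventStructure,
    EventTrigger,
    TextSpan,
    hard_violations,
    validate_document,
)
from .schema import TaskSchema, default_schema
from .tokenize import FUNCTION_POS, Token, segment

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineModel",
    "StackingSource",
    "TriggerCandidate",
    "ArgCandidate",
    "default_generalization_map",
    "train_pipeline",
    "extract_events",
    "detect_triggers",
    "detect_arguments",
    "assemble_events",
    "detect_modifications",
    "stacking_features",
]


# -- semantic class generalization ---------------------------------------

_REGULATION_FAMILY = ("Regulation", "Positive regulation", "Negative regulation")
_ANATOMICAL_SINGLE_THEME = (
    "Cell proliferation",
    "Development",
    "Growth",
    "Death",
    "Breakdown",
    "Remodeling",
)


def default_generalization_map(schema: TaskSchema | None = None) -> dict[str, str]:
    """Event type -> coarse class; total over the schema's event types."""
    schema = schema or default_schema()
    out = {}
    for name in schema.event_types:
        if name in _REGULATION_FAMILY:
            out[name] = "Regulation-class"
        elif name in _ANATOMICAL_SINGLE_THEME:
            out[name] = "Anatomical-process-class"
        else:
            out[name] = name
    return out


# -- candidates ----------------------------------------------------------


@dataclass
class TriggerCandidate:
    span: TextSpan
    surface: str
    event_type: str
    score: float
    sent_idx: int
    tok_idx: int
    key: tuple  # (span, event_type), stable identity


@dataclass
class ArgCandidate:
    source: TriggerCandidate
    target: str | TriggerCandidate  # entity id, or trigger (event-valued)
    role: str  # base role
    score: float

    @property
    def is_event_ref(self) -> bool:
        return isinstance(self.target, TriggerCandidate)

    def target_key(self):
        return self.target.key if self.is_event_ref else self.target


@dataclass(frozen=True)
class StackingSource:
    """A trained source pipeline plus a mapping of its event types onto the
    consuming schema's types; unmapped source types are ignored."""

    model: "PipelineModel"
    type_map: dict[str, str] | None = None

    def map_type(self, event_type: str) -> str | None:
        if self.type_map is None:
            return event_type
        return self.type_map.get(event_type)


@dataclass
class PipelineConfig:
    max_args: int = 4
    max_themes: int = 2
    margin_threshold: float = 0.0
    #: drop accepted combinations strictly contained in a larger accepted
    #: combination of the same trigger
    maximal_only: bool = True
    #: cap on a trigger's argument candidates entering combination
    #: enumeration (kept by descending score)
    max_candidates_per_trigger: int = 8
    train_splits: tuple[str, ...] = ("train", "devel")
    generalization_map: dict[str, str] | None = None


# -- one-versus-rest linear classifier bank ------------------------------


def _as_32bit(X):
    # liblinear accepts only 32-bit sparse indices
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return X


class _MarginBank:
    """One LinearSVC per label over shared vectorized features.

    Labels positive in every training sample degenerate to a constant +1
    margin; labels absent from training never fire.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.vec: DictVectorizer | None = None
        self.classifiers: dict[str, LinearSVC | float] = {}

    def fit(self, samples: list[dict], labelsets: list[frozenset[str]]) -> "_MarginBank":
        self.vec = DictVectorizer()
        X = _as_32bit(self.vec.fit_transform(samples))
        labels = sorted(set().union(*labelsets)) if labelsets else []
        for label in labels:
            y = np.array([label in s for s in labelsets])
            if y.all():
                self.classifiers[label] = 1.0
                continue
            clf = LinearSVC(C=1.0, dual=False, max_iter=5000)
            clf.fit(X, y)
            self.classifiers[label] = clf
        return self

    def margins(self, samples: list[dict]) -> dict[str, np.ndarray]:
        if self.vec is None:
            raise RuntimeError("classifier bank is not trained")
        if not samples:
            return {label: np.empty(0) for label in self.classifiers}
        X = _as_32bit(self.vec.transform(samples))
        out = {}
        for label, clf in self.classifiers.items():
            if isinstance(clf, float):
                out[label] = np.full(X.shape[0], clf)
            else:
                out[label] = clf.decision_function(X)
        return out


@dataclass
class PipelineModel:
    trigger_clf: _MarginBank
    arg_clf: _MarginBank
    assembly_clf: _MarginBank
    mod_clf: _MarginBank | None
    config: PipelineConfig
    generalization: dict[str, str]
    schema: TaskSchema
    stack: StackingSource | None = None
    seed: int = 0


# -- document context ----------------------------------------------------


class _DocContext:
    def __init__(self, doc: AnnotatedDocument):
        self.doc = doc
        self.sentences = segment(doc.text)

    def locate(self, span: TextSpan):
        """(sentence index, first token index, last token index) covering a
        span, or None when no token overlaps it."""
        for s_idx, sent in enumerate(self.sentences):
            cover = [i for i, tok in enumerate(sent) if tok.span.overlaps(span)]
            if cover:
                return s_idx, cover[0], cover[-1]
        return None

    def entities_in_sentence(self, s_idx: int):
        sent = self.sentences[s_idx]
        lo, hi = sent[0].span.start, sent[-1].span.end
        return [
            e
            for e in self.doc.entities.values()
            if lo <= e.span.start and e.span.end <= hi
        ]

    def inside_entity(self, tok: Token) -> bool:
        return any(e.span.overlaps(tok.span) for e in self.doc.entities.values())


# -- stacking features ---------------------------------------------------


def stacking_features(doc: AnnotatedDocument, source_pred: AnnotatedDocument | None,
                      type_map: dict[str, str] | None = None):
    """Index a source model's predictions for feature injection.

    Returns ``(token_types, pair_roles)``: mapped event types per predicted
    trigger span, and roles per (trigger span, target span) pair.  Empty
    predictions yield empty maps, leaving downstream features untouched.
    """
    token_types: dict[TextSpan, set[str]] = {}
    pair_roles: dict[tuple[TextSpan, TextSpan], set[str]] = {}
    if source_pred is None:
        return token_types, pair_roles

    def mapped(event_type: str) -> str | None:
        if type_map is None:
            return event_type
        return type_map.get(event_type)

    for trg in source_pred.triggers.values():
        m = mapped(trg.event_type)
        if m is not None:
            token_types.setdefault(trg.span, set()).add(m)
    for ev in source_pred.events.values():
        trg = source_pred.triggers.get(ev.trigger)
        if trg is None or mapped(ev.event_type) is None:
            continue
        for arg in ev.arguments:
            if arg.is_event_ref:
                sub = source_pred.events.get(arg.target)
                if sub is None:
                    continue
                tspan = source_pred.triggers[sub.trigger].span
            else:
                tspan = source_pred.entities[arg.target].span
            pair_roles.setdefault((trg.span, tspan), set()).add(arg.base_role)
    return token_types, pair_roles


def _run_stack(model: PipelineModel, doc: AnnotatedDocument):
    if model.stack is None:
        return {}, {}
    pred = extract_events(doc, model.stack.model)
    return stacking_features(doc, pred, model.stack.type_map)


# -- feature templates ---------------------------------------------------


def _trigger_sample(
    ctx: _DocContext, s_idx: int, t_idx: int, schema: TaskSchema, stack_tokens
) -> dict:
    sent = ctx.sentences[s_idx]
    tok = sent[t_idx]
    lw = tok.surface.lower()
    fs = {
        f"w={lw}": 1.0,
        f"lemma={tok.lemma}": 1.0,
        f"pos={tok.pos}": 1.0,
        f"chunk={tok.chunk}": 1.0,
    }
    for k in (3, 4):
        if len(lw) > k:
            fs[f"suf{k}={lw[-k:]}"] = 1.0
    for off in (-2, -1, 1, 2):
        j = t_idx + off
        w = sent[j].surface.lower() if 0 <= j < len(sent) else "<pad>"
        fs[f"w[{off}]={w}"] = 1.0
    cats = {
        schema.entity_category(e.entity_type)
        for e in ctx.entities_in_sentence(s_idx)
        if e.entity_type in schema.entity_types
    }
    for c in sorted(cats):
        fs[f"sent-entity-cat={c}"] = 1.0
    for stype in sorted(stack_tokens.get(tok.span, ())):
        fs[f"stack-trigger={stype}"] = 1.0
    return fs


def _pair_sample(
    ctx: _DocContext,
    trigger: TriggerCandidate,
    target_kind: str,
    target_label: str,
    target_surface: str,
    target_span: TextSpan,
    target_tok: int,
    gen: dict[str, str],
    stack_pairs,
) -> dict:
    sent = ctx.sentences[trigger.sent_idx]
    tword = trigger.surface.lower()
    gcls = gen.get(trigger.event_type, trigger.event_type)
    dist = target_tok - trigger.tok_idx
    direction = "R" if dist > 0 else "L"
    bucket = min(abs(dist), 6)
    fs = {
        f"ttype={trigger.event_type}": 1.0,
        f"tclass={gcls}": 1.0,
        f"tword={tword}": 1.0,
        f"target={target_kind}:{target_label}": 1.0,
        f"tclass|target={gcls}|{target_kind}:{target_label}": 1.0,
        f"tsurf|asurf={tword}|{target_surface.lower()}": 1.0,
        f"dir={direction}": 1.0,
        f"dist={bucket}": 1.0,
        f"tclass|dir={gcls}|{direction}": 1.0,
    }
    lo, hi = sorted((trigger.tok_idx, target_tok))
    for j in range(lo + 1, min(hi, lo + 9)):
        fs[f"between={sent[j].surface.lower()}"] = 1.0
    roles = stack_pairs.get((trigger.span, target_span))
    if roles:
        for role in sorted(roles):
            fs[f"stack-arg={role}"] = 1.0
    return fs


def _combo_sample(
    trigger: TriggerCandidate,
    combo: tuple[tuple[str, str, str], ...],  # (role, target_kind, target_label)
    available: tuple[tuple[str, str], ...],  # (role, target_kind) candidate pool
    gen: dict[str, str],
) -> dict:
    gcls = gen.get(trigger.event_type, trigger.event_type)
    sig = "+".join(sorted(f"{r}:{k}" for r, k, _ in combo)) or "<empty>"
    fs = {
        f"ttype={trigger.event_type}": 1.0,
        f"tclass={gcls}": 1.0,
        f"tword={trigger.surface.lower()}": 1.0,
        f"nargs={len(combo)}": 1.0,
        f"sig={sig}": 1.0,
        f"ttype|sig={trigger.event_type}|{sig}": 1.0,
        f"tclass|sig={gcls}|{sig}": 1.0,
    }
    for role, kind, label in combo:
        fs[f"arg={role}:{kind}:{label}"] = 1.0
        fs[f"tclass|arg={gcls}|{role}:{kind}"] = 1.0
    # candidate-pool context: which proposed arguments the combination
    # leaves out — a Theme-only combination reads differently when a Cause
    # candidate was on the table
    fs[f"n_avail={len(available)}"] = 1.0
    taken = [(r, k) for r, k, _ in combo]
    omitted = list(available)
    for item in taken:
        if item in omitted:
            omitted.remove(item)
    for role, kind in omitted:
        fs[f"omitted={role}:{kind}"] = 1.0
        fs[f"tclass|omitted={gcls}|{role}:{kind}"] = 1.0
    fs[f"n_omitted={len(omitted)}"] = 1.0
    return fs


def _mod_sample(
    ctx: _DocContext, trigger: TriggerCandidate, event_type: str, gen: dict[str, str]
) -> dict:
    sent = ctx.sentences[trigger.sent_idx]
    gcls = gen.get(event_type, event_type)
    fs = {
        f"ttype={event_type}": 1.0,
        f"tclass={gcls}": 1.0,
        f"tword={trigger.surface.lower()}": 1.0,
    }
    for off in range(-4, 5):
        j = trigger.tok_idx + off
        if 0 <= j < len(sent) and off != 0:
            w = sent[j].surface.lower()
            fs[f"ctx={w}"] = 1.0
            fs[f"ctx[{'-' if off < 0 else '+'}]={w}"] = 1.0
    fs[f"sent-start={sent[0].surface.lower()}"] = 1.0
    return fs


# -- gold decomposition for training -------------------------------------


def _gold_trigger_candidates(ctx: _DocContext) -> dict[str, TriggerCandidate]:
    """Gold triggers as candidates keyed by trigger id (head = last token)."""
    out = {}
    for trg in ctx.doc.triggers.values():
        loc = ctx.locate(trg.span)
        if loc is None:
            continue
        s_idx, _, last = loc
        out[trg.id] = TriggerCandidate(
            span=trg.span,
            surface=trg.surface,
            event_type=trg.event_type,
            score=0.0,
            sent_idx=s_idx,
            tok_idx=last,
            key=(trg.span, trg.event_type),
        )
    return out


def _target_descriptor(ctx: _DocContext, doc, target, schema: TaskSchema):
    """(kind, label, surface, span, head token) for an entity id or trigger
    candidate; None when the target is outside any sentence."""
    if isinstance(target, TriggerCandidate):
        return ("event", target.event_type, target.surface, target.span, target.tok_idx)
    ent = doc.entities[target]
    loc = ctx.locate(ent.span)
    if loc is None:
        return None
    cat = (
        schema.entity_category(ent.entity_type)
        if ent.entity_type in schema.entity_types
        else ent.entity_type
    )
    return ("entity", cat, ent.surface, ent.span, loc[2])


def _role_schema_ok(
    schema: TaskSchema, trigger_type: str, role: str, target, doc
) -> bool:
    if role not in schema.allowed_roles(trigger_type):
        return False
    if role == "Theme" and not isinstance(target, TriggerCandidate):
        constraint = schema.theme_constraint(trigger_type)
        if constraint is not None:
            ent = doc.entities[target]
            if ent.entity_type not in schema.entity_types:
                return True
            if schema.entity_category(ent.entity_type) not in constraint:
                return False
    return True


def _enumerate_combos(cands: list[ArgCandidate], config: PipelineConfig):
    """Role-consistent subsets: distinct targets, ≤1 of each non-Theme
    role, ≤ max_themes Themes, ≤ max_args total; includes the empty set."""
    combos: list[tuple[ArgCandidate, ...]] = [()]
    for size in range(1, min(config.max_args, len(cands)) + 1):
        for combo in combinations(cands, size):
            targets = [c.target_key() for c in combo]
            if len(set(targets)) != len(targets):
                continue
            role_counts: dict[str, int] = {}
            for c in combo:
                role_counts[c.role] = role_counts.get(c.role, 0) + 1
            if role_counts.get("Theme", 0) > config.max_themes:
                continue
            if any(n > 1 for r, n in role_counts.items() if r != "Theme"):
                continue
            combos.append(combo)
    return combos


# -- training ------------------------------------------------------------


def train_pipeline(
    corpus: Corpus,
    config: PipelineConfig | None = None,
    seed: int = 0,
    stack: StackingSource | None = None,
    schema: TaskSchema | None = None,
) -> PipelineModel:
    """Train the four stage models on gold annotation.

    Stages 1–2 train on gold triggers and gold trigger/argument pairs;
    stages 3–4 on candidates derived from gold structures (each gold
    event's exact argument combination is a positive, every other
    role-consistent combination over that trigger's gold pairs a
    negative).  Deterministic given corpus, config and seed.
    """
    config = config or PipelineConfig()
    schema = schema or default_schema()
    gen = config.generalization_map or default_generalization_map(schema)
    docs = list(corpus.documents(config.train_splits))
    if not docs:
        raise ValueError("empty training split")
    if not any(doc.events for doc in docs):
        raise ValueError("training corpus contains no event annotations")

    trig_X: list[dict] = []
    trig_y: list[frozenset[str]] = []
    arg_X: list[dict] = []
    arg_y: list[frozenset[str]] = []
    asm_X: list[dict] = []
    asm_y: list[frozenset[str]] = []
    mod_X: list[dict] = []
    mod_y: list[frozenset[str]] = []

    stack_model = None
    if stack is not None:
        stack_model = stack.model

    for doc in docs:
        ctx = _DocContext(doc)
        if stack_model is not None:
            src_pred = extract_events(doc, stack_model)
            stack_tokens, stack_pairs = stacking_features(doc, src_pred, stack.type_map)
        else:
            stack_tokens, stack_pairs = {}, {}

        # stage 1: tokens -> event types
        gold_types: dict[tuple[int, int], set[str]] = {}
        gold_cands = _gold_trigger_candidates(ctx)
        for tc in gold_cands.values():
            gold_types.setdefault((tc.sent_idx, tc.tok_idx), set()).add(tc.event_type)
        for s_idx, sent in enumerate(ctx.sentences):
            for t_idx, tok in enumerate(sent):
                if tok.pos in FUNCTION_POS or ctx.inside_entity(tok):
                    continue
                trig_X.append(_trigger_sample(ctx, s_idx, t_idx, schema, stack_tokens))
                trig_y.append(frozenset(gold_types.get((s_idx, t_idx), ())))

        # stage 2: gold trigger x same-sentence target -> roles
        events_by_trigger: dict[str, list[EventStructure]] = {}
        for ev in doc.events.values():
            events_by_trigger.setdefault(ev.trigger, []).append(ev)

        gold_pair_roles: dict[str, dict] = {}
        for tid, tc in gold_cands.items():
            pair_roles: dict = {}
            for ev in events_by_trigger.get(tid, []):
                for arg in ev.arguments:
                    if arg.is_event_ref:
                        sub_tid = doc.events[arg.target].trigger
                        if sub_tid not in gold_cands:
                            continue
                        target = gold_cands[sub_tid]
                        tkey = target.key
                    else:
                        target = arg.target
                        tkey = arg.target
                    pair_roles.setdefault(tkey, (target, set()))[1].add(arg.base_role)
            gold_pair_roles[tid] = pair_roles

            targets: list = [
                e.id
                for e in ctx.entities_in_sentence(tc.sent_idx)
            ]
            targets += [
                other
                for oid, other in gold_cands.items()
                if oid != tid and other.sent_idx == tc.sent_idx
            ]
            for target in targets:
                desc = _target_descriptor(ctx, doc, target, schema)
                if desc is None:
                    continue
                kind, label, surface, span, head = desc
                tkey = target.key if isinstance(target, TriggerCandidate) else target
                roles = pair_roles.get(tkey, (None, set()))[1]
                roles = {
                    r
                    for r in roles
                    if _role_schema_ok(schema, tc.event_type, r, target, doc)
                }
                arg_X.append(
                    _pair_sample(ctx, tc, kind, label, surface, span, head, gen, stack_pairs)
                )
                arg_y.append(frozenset(roles))

        # stage 3: combinations over gold pairs; stage 4: gold events
        for tid, tc in gold_cands.items():
            pair_roles = gold_pair_roles.get(tid, {})
            cands: list[ArgCandidate] = []
            for target, roles in pair_roles.values():
                for role in sorted(roles):
                    cands.append(ArgCandidate(tc, target, role, 0.0))
            gold_sets = set()
            for ev in events_by_trigger.get(tid, []):
                sig = []
                ok = True
                for arg in ev.arguments:
                    if arg.is_event_ref:
                        sub_tid = doc.events[arg.target].trigger
                        if sub_tid not in gold_cands:
                            ok = False
                            break
                        sig.append((arg.base_role, gold_cands[sub_tid].key))
                    else:
                        sig.append((arg.base_role, arg.target))
                if ok:
                    gold_sets.add(frozenset(sig))
            available = tuple(
                (c.role, _desc_kind_label(ctx, doc, c, schema)[0]) for c in cands
            )
            for combo in _enumerate_combos(cands, config):
                sig = frozenset((c.role, c.target_key()) for c in combo)
                desc_combo = tuple(
                    (c.role, *_desc_kind_label(ctx, doc, c, schema)) for c in combo
                )
                asm_X.append(_combo_sample(tc, desc_combo, available, gen))
                asm_y.append(frozenset(["event"]) if sig in gold_sets else frozenset())

            for ev in events_by_trigger.get(tid, []):
                mod_X.append(_mod_sample(ctx, tc, ev.event_type, gen))
                mod_y.append(doc.modification_flags(ev.id))

    trigger_clf = _MarginBank(seed).fit(trig_X, trig_y)
    arg_clf = _MarginBank(seed).fit(arg_X, arg_y)
    assembly_clf = _MarginBank(seed).fit(asm_X, asm_y)
    mod_clf = None
    if any(mod_y):
        mod_clf = _MarginBank(seed).fit(mod_X, mod_y)
    logger.info(
        "trained pipeline: %d trigger, %d argument, %d assembly, %d modification samples",
        len(trig_X),
        len(arg_X),
        len(asm_X),
        len(mod_X),
    )
    return PipelineModel(
        trigger_clf=trigger_clf,
        arg_clf=arg_clf,
        assembly_clf=assembly_clf,
        mod_clf=mod_clf,
        config=config,
        generalization=gen,
        schema=schema,
        stack=stack,
        seed=seed,
    )


def _desc_kind_label(ctx, doc, cand: ArgCandidate, schema) -> tuple[str, str]:
    desc = _target_descriptor(ctx, doc, cand.target, schema)
    if desc is None:
        return ("entity", "?")
    return desc[0], desc[1]


# -- prediction ----------------------------------------------------------


def detect_triggers(
    doc: AnnotatedDocument, model: PipelineModel, ctx: _DocContext | None = None,
    stack_tokens=None,
) -> list[TriggerCandidate]:
    """Stage 1: score content-word tokens; emit one candidate per
    (token span, type) with positive margin."""
    if model.trigger_clf.vec is None:
        raise RuntimeError("pipeline model is not trained")
    ctx = ctx or _DocContext(doc)
    if stack_tokens is None:
        stack_tokens = _run_stack(model, doc)[0]
    positions = []
    samples = []
    for s_idx, sent in enumerate(ctx.sentences):
        for t_idx, tok in enumerate(sent):
            if tok.pos in FUNCTION_POS or ctx.inside_entity(tok):
                continue
            positions.append((s_idx, t_idx))
            samples.append(_trigger_sample(ctx, s_idx, t_idx, model.schema, stack_tokens))
    margins = model.trigger_clf.margins(samples)
    out = []
    for etype in sorted(margins):
        scores = margins[etype]
        for (s_idx, t_idx), score in zip(positions, scores):
            if score > model.config.margin_threshold:
                tok = ctx.sentences[s_idx][t_idx]
                out.append(
                    TriggerCandidate(
                        span=tok.span,
                        surface=tok.surface,
                        event_type=etype,
                        score=float(score),
                        sent_idx=s_idx,
                        tok_idx=t_idx,
                        key=(tok.span, etype),
                    )
                )
    out.sort(key=lambda c: (c.span, c.event_type))
    return out


def detect_arguments(
    doc: AnnotatedDocument,
    triggers: list[TriggerCandidate],
    model: PipelineModel,
    ctx: _DocContext | None = None,
    stack_pairs=None,
) -> list[ArgCandidate]:
    """Stage 2: role-score trigger/target pairs within the sentence.

    Pairs breaking a schema constraint are filtered before classification;
    every returned candidate's role is allowed for its trigger type.
    """
    ctx = ctx or _DocContext(doc)
    if stack_pairs is None:
        stack_pairs = _run_stack(model, doc)[1]
    gen = model.generalization
    meta = []
    samples = []
    for tc in triggers:
        targets: list = [e.id for e in ctx.entities_in_sentence(tc.sent_idx)]
        targets += [o for o in triggers if o.key != tc.key and o.sent_idx == tc.sent_idx]
        for target in targets:
            desc = _target_descriptor(ctx, doc, target, model.schema)
            if desc is None:
                continue
            kind, label, surface, span, head = desc
            meta.append((tc, target))
            samples.append(
                _pair_sample(ctx, tc, kind, label, surface, span, head, gen, stack_pairs)
            )
    margins = model.arg_clf.margins(samples)
    out = []
    for role in sorted(margins):
        scores = margins[role]
        for (tc, target), score in zip(meta, scores):
            if score <= model.config.margin_threshold:
                continue
            if not _role_schema_ok(model.schema, tc.event_type, role, target, doc):
                continue
            out.append(ArgCandidate(tc, target, role, float(score)))
    return out


def assemble_events(
    trigger: TriggerCandidate,
    arg_candidates: list[ArgCandidate],
    model: PipelineModel,
    ctx: _DocContext,
    doc: AnnotatedDocument,
    resolve_event,
) -> list[tuple[float, tuple[ArgCandidate, ...]]]:
    """Stage 3 for one trigger: classify role-consistent combinations of
    its argument candidates; return accepted ``(margin, combination)``
    pairs.  ``resolve_event`` maps an event-valued candidate to an emitted
    sub-event id (or None, dropping the candidate)."""
    cands = [c for c in arg_candidates if c.source.key == trigger.key]
    cands.sort(key=lambda c: -c.score)
    if len(cands) > model.config.max_candidates_per_trigger:
        cands = cands[: model.config.max_candidates_per_trigger]
    resolved: list[ArgCandidate] = []
    for c in cands:
        if c.is_event_ref and resolve_event(c.target) is None:
            continue
        resolved.append(c)
    combos = _enumerate_combos(resolved, model.config)
    available = tuple(
        (c.role, _desc_kind_label(ctx, doc, c, model.schema)[0]) for c in resolved
    )
    samples = [
        _combo_sample(
            trigger,
            tuple((c.role, *_desc_kind_label(ctx, doc, c, model.schema)) for c in combo),
            available,
            model.generalization,
        )
        for combo in combos
    ]
    margins = model.assembly_clf.margins(samples).get("event")
    if margins is None:
        return []
    accepted = [
        (float(m), combo)
        for m, combo in zip(margins, combos)
        if m > model.config.margin_threshold
    ]
    if model.config.maximal_only and accepted:
        sigs = [frozenset((c.role, c.target_key()) for c in combo) for _, combo in accepted]
        keep = []
        for i, (m, combo) in enumerate(accepted):
            if any(j != i and sigs[i] < sigs[j] for j in range(len(accepted))):
                continue
            keep.append((m, combo))
        accepted = keep
    return accepted


def detect_modifications(
    doc: AnnotatedDocument,
    events: list[tuple[str, TriggerCandidate, str]],  # (event id, trigger, type)
    model: PipelineModel,
    ctx: _DocContext,
) -> list[EventModification]:
    """Stage 4: flag assembled events for Negation / Speculation."""
    if model.mod_clf is None or not events:
        return []
    samples = [
        _mod_sample(ctx, tc, etype, model.generalization) for _, tc, etype in events
    ]
    margins = model.mod_clf.margins(samples)
    out = []
    n_mod = 0
    for kind in sorted(margins):
        for (eid, _, _), score in zip(events, margins[kind]):
            if score > model.config.margin_threshold:
                n_mod += 1
                out.append(EventModification(f"M{n_mod}", kind, eid))
    return out


def extract_events(doc: AnnotatedDocument, model: PipelineModel) -> AnnotatedDocument:
    """Run the full pipeline on a document with entity annotations.

    Returns a new document sharing text and entities, holding predicted
    triggers, events and modifications.  Orphan triggers (whose every
    combination was rejected) are dropped.  The output always passes
    structural and schema validation.
    """
    if not doc.entities:
        # extraction presumes entity annotations; nothing to anchor events on
        result = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
        return result
    ctx = _DocContext(doc)
    stack_tokens, stack_pairs = _run_stack(model, doc)
    triggers = detect_triggers(doc, model, ctx, stack_tokens)
    arg_cands = detect_arguments(doc, triggers, model, ctx, stack_pairs)

    # bottom-up order over the trigger-reference graph (Kahn); candidates on
    # cyclic paths are dropped, logged
    by_key = {tc.key: tc for tc in triggers}
    deps: dict[tuple, set[tuple]] = {tc.key: set() for tc in triggers}
    for c in arg_cands:
        if c.is_event_ref:
            deps[c.source.key].add(c.target.key)
    order: list[tuple] = []
    ready = [k for k, d in deps.items() if not d]
    remaining = {k: set(d) for k, d in deps.items()}
    for k in list(remaining):
        if not remaining[k]:
            del remaining[k]
    while ready:
        ready.sort()
        k = ready.pop(0)
        order.append(k)
        for other, d in list(remaining.items()):
            d.discard(k)
            if not d:
                del remaining[other]
                ready.append(other)
    if remaining:
        logger.info(
            "dropping event-valued candidates on %d cycle-involved triggers",
            len(remaining),
        )
        cycle_keys = set(remaining)
        arg_cands = [
            c for c in arg_cands if not (c.is_event_ref and c.target.key in cycle_keys)
        ]
        order.extend(sorted(cycle_keys))

    result = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
    result.entities.update(doc.entities)
    next_t = 1 + max(
        (int(i[1:]) for i in doc.entities if i[1:].isdigit()), default=0
    )
    best_event: dict[tuple, tuple[float, str]] = {}  # trigger key -> (margin, eid)
    trigger_ids: dict[tuple, str] = {}
    emitted: list[tuple[str, TriggerCandidate, str]] = []
    n_events = 0

    def resolve_event(target: TriggerCandidate):
        entry = best_event.get(target.key)
        return entry[1] if entry else None

    for key in order:
        tc = by_key[key]
        accepted = assemble_events(tc, arg_cands, model, ctx, doc, resolve_event)
        if not accepted:
            continue
        if key not in trigger_ids:
            tid = f"T{next_t}"
            next_t += 1
            trigger_ids[key] = tid
            result.triggers[tid] = EventTrigger(tid, tc.event_type, tc.span, tc.surface)
        for margin, combo in sorted(accepted, key=lambda mc: -mc[0]):
            n_events += 1
            eid = f"E{n_events}"
            args = []
            theme_n = 0
            def _arg_order(c: ArgCandidate):
                span = (
                    c.target.span
                    if c.is_event_ref
                    else doc.entities[c.target].span
                )
                return (c.role, span.start)

            for c in sorted(combo, key=_arg_order):
                if c.is_event_ref:
                    target_id = resolve_event(c.target)
                else:
                    target_id = c.target
                role = c.role
                if role == "Theme":
                    theme_n += 1
                    if theme_n > 1:
                        role = f"Theme{theme_n}"
                args.append(EventArgument(role, target_id))
            result.events[eid] = EventStructure(
                eid, tc.event_type, trigger_ids[key], tuple(args)
            )
            emitted.append((eid, tc, tc.event_type))
            prev = best_event.get(key)
            if prev is None or margin > prev[0]:
                best_event[key] = (margin, eid)

    for mod in detect_modifications(doc, emitted, model, ctx):
        result.modifications[mod.id] = mod

    bad = hard_violations(validate_document(result, model.schema))
    if bad:  # defensive; stage logic should prevent this
        logger.warning("extracted document has violations: %s", bad[:3])
    return result
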