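# Methods

This note documents the models and procedures implemented in `mlevent`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Task and representation

The target is multi-level biomedical event extraction in the MLEE style:
documents carry typed entity mentions at every level of biological
organization (14 types in three informal categories — Organism, Anatomy,
Molecule) and typed events (19 types in four categories — Anatomical,
Molecular, General, Planned).  An event is an n-ary association of a
*trigger* span with role-labelled arguments; arguments may be entities or
other events, so structures nest (regulation of regulation of growth).
Two binary modifications, Negation and Speculation, attach to events.

Annotation is stored in the BioNLP shared-task standoff dialect: `.txt`
for text, `.a1` for entities, `.a2` for triggers (`T`), events (`E`) and
modifications (`M`), with 0-based half-open character offsets.  MLEE type
names contain spaces ("Multi-tissue structure"), so the parser splits the
type/offset field from the right and terminates a multi-word event type at
the first `:`.  Relation, equivalence and normalization lines are out of
scope.  Serialization validates first; orphan triggers (a legitimate state
for predicted output whose events were all rejected) are reported by
validation as warnings but do not block writing.

The schema — type names, categories, role inventories, and the Theme
restriction (Anatomical events take Organism/Anatomy Themes, Molecular
events take Molecule Themes, others are unrestricted; event-valued Themes
are never restricted) — ships as a declarative YAML file, so a different
task schema can be dropped in.  Site arguments are deliberately left
unrestricted.  Ontology cross-references are inert metadata.

## Entity mention detection

A single linear-chain sequence labeler jointly predicts all entity types
over BIO-encoded tokens.  The labeler is an averaged structured
perceptron: emission weights over (feature, label) pairs plus label
transition weights with a distinguished start state, Viterbi decoding,
whole-sequence perceptron updates, weights averaged over epoch snapshots
(default 10 epochs; training order shuffled by a seeded generator, so
training is deterministic given corpus, configuration and seed).

Features per token cover four families: orthographic (collapsed character
shape, case/digit/hyphen flags, prefixes and suffixes of length 2–4),
lexical (surface, lemma, ±2 token context window, preceding bigram),
syntactic (POS and chunk tags from a pluggable tagger; the shipped default
is a rule-based tagger with a coarse tagset and NP/VP chunking), and
dictionary flags.  Dictionary features are B/I-positioned per lexicon:
greedy leftmost-longest matching over normalized forms (case-folded,
punctuation collapsed — a hyphenated token contributes its subwords), with
the first matched token flagged `B` and the rest `I`.

Gold spans are snapped outward to token boundaries for encoding; nested or
overlapping gold entities are resolved by the longest-span rule (a linear
chain cannot express nesting) and discards are logged.  Decoding repairs
dangling `I-` labels by promotion to `B-`.

Two configurations mirror the standard experimental contrast: *base*
(no lexicons) and *dictionary* (lexicon flags added).  On the synthetic
benchmark the dictionary model's advantage comes from category-ambiguous
unseen names (see below), which is also where dictionaries earn their keep
on real text.

## Event extraction pipeline

Four stages in fixed order, each a one-versus-rest linear classifier bank
(scikit-learn `LinearSVC`, L2-regularized squared hinge, C = 1, margin
threshold 0; a candidate with no positive margin is rejected):

1. **Trigger detection.**  Every content-word token outside an entity span
   is scored against all event types (multi-label); positive margins
   become single-token typed triggers.  Multi-token gold triggers
   contribute their last token at training time; approximate-span
   evaluation absorbs the difference at scoring time.
2. **Argument detection.**  Trigger × target pairs within a sentence
   (targets: entities and other triggers) are scored over roles.  Pairs
   violating the schema (role not allowed for the trigger's type, or an
   entity-valued Theme outside the type's category restriction) are
   filtered before classification.
3. **Event assembly.**  For each trigger, role-consistent combinations of
   its accepted argument candidates are enumerated — distinct targets, at
   most one of each non-Theme role, up to `max_themes` (2) Themes, at most
   `max_args` (4) arguments, including the empty combination (trigger-only
   events such as "angiogenesis" exist) — and classified.  Combination
   features include the argument signature and, critically, the *candidate
   pool context*: which proposed arguments the combination leaves out.
   Without the omitted-candidate features a Theme-only combination is
   indistinguishable from the same combination when a Cause candidate was
   also available, and the classifier collapses to the majority decision.
   Accepted combinations become events; with `maximal_only` (default on)
   an accepted combination strictly contained in a larger accepted
   combination of the same trigger is dropped.  Event-valued arguments are
   resolved bottom-up: triggers are processed in topological order of the
   candidate reference graph, an event-valued candidate resolves to the
   best-scoring event already emitted for its target trigger, and
   candidates on cyclic paths are dropped (logged), so output is acyclic
   by construction.
4. **Modification detection.**  Each assembled event is scored for
   Negation and Speculation from trigger-window and sentence-cue features.

Semantic class generalization maps the three Regulation types to one
coarse class and the six single-Theme anatomical process types to another;
feature templates are emitted per-type and per-class, sharing statistics
across sparse types.  Stages 1–2 train on gold triggers and gold pairs;
stages 3–4 on gold-derived candidates (each gold event's exact argument
set is a positive, every other enumerated combination over that trigger's
gold pairs a negative).

*Stacking*: a source pipeline model's predictions on the same text can be
injected as features (predicted trigger types per token at stage 1,
predicted roles per span pair at stage 2) after mapping the source's event
types onto the consuming schema; unmapped types are ignored, and empty
source predictions leave features untouched.  Stacking helps when the
target corpus is sparse: in the packaged experiment a model trained on a
24-document corpus gains 3–8 F points from features of a source model
trained on an independent 150-document corpus, while with 80+ target
documents the base model saturates and stacking is a wash.

Degenerate inputs: a document without entity annotations yields no events
(extraction presumes the entity layer); an untrained model raises.

## Evaluation protocols

Entity mentions are matched under exact-span, left-boundary or
right-boundary criteria, always requiring identical types.  Events are
matched by recursive structural comparison — equal types, matching
triggers, and role-for-role matching arguments (repeated Themes pair
order-insensitively) — with two relaxations, both on by default as the
primary criteria:

* *approximate span*: the predicted trigger span must lie within the gold
  span extended by one whitespace word on each side;
* *approximate recursive*: once comparison descends through an
  event-valued argument, sub-events are compared on type, trigger and
  Theme arguments only.

Both relaxations strictly enlarge the per-pair match relation, so
tp(relaxed) ≥ tp(strict) for any fixed predictions; the same holds for the
boundary criteria versus exact match.

Counts are micro-averaged (summed over documents before P/R/F).  Within a
document, pairing is a maximum one-to-one bipartite matching
(Hopcroft–Karp) — well-defined regardless of iteration order, and because
matches require equal types the problem decomposes by type and
per-category counts sum exactly to the overall counts.  Conventions:
P (or R) is 0 on a zero denominator; F = 0 when P + R = 0.  The
Modification row scores flags on matched events: a predicted flag is a
true positive iff its event matched a gold event carrying the same flag;
flags on unmatched events count as false positives (this choice is noted
in the report footer).

The cross-level statistic is the fraction of events whose transitive
argument closure (following event-valued arguments) contains a Molecule
entity and at least one Organism/Anatomy entity.

## Synthetic corpus generator

The generator emulates the MLEE summary distributions at desk scale so the
whole system is trainable and testable without downloads.  Documents are
built sentence by sentence from templated clauses ("We observed inhibition
of growth of tumours by VEGF .") over a small biomedical vocabulary seeded
from the published type examples; gold annotation is constructed together
with the text, so every document parses, validates and round-trips by
construction.

Defaults follow the published corpus figures: split proportions
131/44/87, entity-type and event-type weights equal to the published
annotation counts, cross-level rate 0.18.  Values the corpus summary does
not report were fixed once at field-plausible levels: Negation 0.06 and
Speculation 0.05 per generated unit, nesting continuation 0.5 with maximum
depth 3, 8–12 sentences per document, 15% annotation-light filler
sentences, per-role attachment rates (Cause 0.45, Site 0.15, AtLoc 0.4,
second Theme 0.2, Instrument 0.4), trigger-only rate 0.5 for blood-vessel
development events (whose triggers, like "angiogenesis", incorporate the
affected entity), and a 0.25 novel-surface rate.

Three properties are engineered to hold exactly in expectation, with the
required constants derived from the configuration rather than tuned:

* **Type marginals.**  Every generated event's type is drawn so its
  marginal probability is proportional to the configured weight.
  Non-cross units choose a side (anatomical or molecular); shared
  (General/Planned) types have their weights halved on each side, and the
  side probability is weighted by each side's weight mass *divided by its
  expected tree size* — molecular-side trees nest more because regulation
  is a larger share of that side's mass, and without the inverse-size
  correction molecular-side events would be overrepresented.
* **Cross-level rate.**  Cross-level events are dedicated single-event
  units (a General/Planned type combining a molecular with an anatomical
  participant, e.g. "inhibition of tumours by bevacizumab"); all other
  units keep their entities on one level.  With target fraction f and
  expected non-cross unit size s (computed from the nesting recurrence
  T(d) = 1 + q·p·T(d+1), q the regulation share of the side), the
  per-unit cross probability c = f·s / (1 − f + f·s) makes the expected
  event-level fraction exactly f; the non-cross weights of General/Planned
  types are reduced by the compensating factor so the type marginals above
  still hold.  f = 0 yields exactly zero cross-level events.
* **Determinism.**  One seeded generator drives every choice; identical
  configurations produce byte-identical corpora.

Novel surfaces: a quarter of gene-product, drug and cell mentions use
open-ended name patterns, and gene products and cell lines share one bare
alphanumeric code space ("QR-7"), so held-out splits contain mentions
whose surface shape cannot decide the category.  The paired lexicons
(per entity category, default 0.8 coverage of the realized corpus
vocabulary plus distractor entries) are what resolves them — giving the
dictionary NER configuration its genuine, reproducible advantage over the
base configuration.

What the generator does not emulate: natural-language fluency and
syntactic variety, annotator disagreement, discontinuous or nested gold
mentions, cross-sentence arguments, and the long-tail lexical ambiguity of
real abstracts.  Scores on this benchmark are therefore ceilings on
component correctness and learnability, not estimates of performance on
real text — on the real corpus the published scores are ~76.5 F for
dictionary-supported mention detection and ~53.4 F for stacked event
extraction, far below the synthetic benchmark's ~96–99 F.

## Benchmark sizes and numerical choices

The packaged experiments use a 200-document corpus (~2000 events,
~1300 sentences): large enough that the cross-level calibration check
(±0.03) and the 3-standard-error category-proportion checks are
comfortably powered, and small enough that the full suite trains every
model from scratch in seconds.  Training uses the train+devel splits and
evaluation the held-out test split.  Stage classifiers use `LinearSVC`
with `dual=False` (deterministic primal solve); the perceptron runs 10
epochs; combination enumeration is capped at the 8 highest-scoring
candidates per trigger.  Ties in Viterbi and in argmax selections resolve
to the lowest index, fixed by sorted iteration orders throughout.

## Known limitations

* Predicted triggers are single tokens; multi-token triggers are only
  recovered up to approximate-span matching.
* The rule-based tagger is deliberately coarse; a better tagger can be
  plugged in, and feature quality on real text would depend on it.
* The assembly stage enumerates combinations independently per trigger;
  there is no joint decoding across triggers.
* Lexicon matching is exact (after normalization); no fuzzy or
  morphological matching.
* The Modification row's false-positive convention for unmatched events is
  one of two defensible readings of the protocol; the alternative
  (ignoring them) would raise the Modification precision.
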