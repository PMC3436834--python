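# mlevent — multi-level biomedical event extraction

`mlevent` is a toolkit for extracting *multi-level events* from biomedical
text in the MLEE style: structured statements that connect molecules,
cells, tissues, organs and organisms — for example, that a gene product
negatively regulates the growth of a tumour.  It is aimed at biomedical
text-mining practitioners who work with BioNLP-style standoff annotation
and want a complete, desk-scale, dependency-light implementation of the
task: the data model, the type schema, trainable extraction models, the
standard evaluation protocols, and a seeded synthetic corpus generator so
everything is testable without downloading any corpus.

## The representation and the models

An **entity mention** is a continuous typed span (14 types in three
categories: Organism, Anatomy, Molecule).  An **event** is an n-ary
association `E = (type, trigger, {role_i : arg_i})`, where the trigger is
the text span stating the event, roles come from {Theme, Cause, Site,
AtLoc, FromLoc, ToLoc, Instrument}, and each argument is an entity or
another event — so structures nest, as in

```
E1  Negative regulation(trigger="inhibition", Theme=E2, Cause=VEGF)
E2  Growth(trigger="growth", Theme=tumours)
```

Events carry optional Negation / Speculation flags.  Annotation lives in
the `.txt / .a1 / .a2` standoff format with 0-based half-open offsets.

**Entity mention detection** is joint sequence labeling over BIO-encoded
tokens — an averaged structured perceptron with Viterbi decoding, with
orthographic, lexical, syntactic and dictionary-match features.  A *base*
configuration uses no lexicons; a *dictionary* configuration adds
B/I-positioned match flags from per-category lexicons.

**Event extraction** is a four-stage pipeline over gold or predicted
entities — trigger detection, argument detection, multi-argument event
assembly, modification detection — each stage a bank of one-versus-rest
linear SVMs with margin threshold 0, with semantic-class generalization
(regulation types merged, single-Theme anatomical types merged) and
optional *stacking* of a source model's predictions as features.

**Evaluation** is micro-averaged precision / recall / F,

    P = 100·tp/(tp+fp),  R = 100·tp/(tp+fn),  F = 2PR/(P+R),

with maximum one-to-one matching between gold and predicted annotations.
Entity matching supports exact, left-boundary and right-boundary criteria;
event matching is recursive over the argument structure and supports the
*approximate span* relaxation (predicted trigger within the gold span
extended one word each way) and the *approximate recursive* relaxation
(sub-events compared on type, trigger and Themes only) — both on in the
primary criteria.  Reports give overall and per-category rows plus a
Modification row, and corpus statistics include the *cross-level
fraction*: the share of events whose argument closure reaches both the
molecular and the organism/anatomy level.

## Worked example

Generate a 200-document synthetic corpus, train both mention detectors and
the event pipeline, and score the held-out test split:

```python
import logging; logging.basicConfig(level=logging.ERROR)
from mlevent import (
    GeneratorConfig, generate_corpus, generate_lexicons,
    train_ner, predict_entities, train_pipeline, extract_events,
    evaluate_ner, evaluate_events, cross_level_fraction, AnnotatedDocument,
)

config = GeneratorConfig(seed=1, n_documents=200)
corpus = generate_corpus(config)
lexicons = generate_lexicons(config, corpus)
print(f"documents: {len(corpus)}  "
      f"events: {sum(len(d.events) for d in corpus.documents())}  "
      f"cross-level fraction: {cross_level_fraction(corpus):.3f}")

base = train_ner(corpus, seed=1)
dictionary = train_ner(corpus, lexicons=list(lexicons.values()), seed=1)
test = corpus.splits["test"]

def ner_predictions(model):
    out = []
    for doc in test:
        pred = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
        for ent in predict_entities(model, doc):
            pred.entities[ent.id] = ent
        out.append(pred)
    return out

for name, model in [("base", base), ("dictionary", dictionary)]:
    prf = evaluate_ner(test, ner_predictions(model), "exact").overall
    print(f"NER {name:10s} exact P/R/F = "
          f"{prf.precision:.2f} / {prf.recall:.2f} / {prf.f_score:.2f}")

pipeline = train_pipeline(corpus, seed=1)
preds = []
for doc in test:
    inp = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
    inp.entities.update(doc.entities)          # gold entities given
    preds.append(extract_events(inp, pipeline))
report = evaluate_events(test, preds)          # primary criteria
prf = report.overall
print(f"events (primary criteria) P/R/F = "
      f"{prf.precision:.2f} / {prf.recall:.2f} / {prf.f_score:.2f}")
for category, counts in report.rows.items():
    print(f"  {category:<12} tp={counts.tp:<4} fp={counts.fp:<3} "
          f"fn={counts.fn:<3} F={report.prf(category).f_score:.2f}")
```

prints

```
documents: 200  events: 2035  cross-level fraction: 0.189
NER base       exact P/R/F = 98.00 / 98.00 / 98.00
NER dictionary exact P/R/F = 99.79 / 99.79 / 99.79
events (primary criteria) P/R/F = 96.54 / 95.39 / 95.96
  Anatomical   tp=158  fp=1   fn=1   F=99.37
  Molecular    tp=47   fp=0   fn=1   F=98.95
  General      tp=371  fp=22  fn=29  F=93.57
  Planned      tp=66   fp=0   fn=0   F=100.00
```

Reading the output: the realized cross-level fraction sits at its
configured 0.18 target; lexicon features lift exact-match mention
detection (their gain comes from test-split names never seen in training
whose category only the lexicon can decide); and the pipeline reconstructs
nested event structures on held-out documents at ~96 F under the primary
criteria, with anatomical-process events the most reliable category.
Scores this high reflect the templated regularity of the synthetic
benchmark — on the real MLEE corpus the published state of the art is
~76.5 F for dictionary-supported mention detection and ~53.4 F for stacked
event extraction (see `docs/methods.md` for what the generator does and
does not emulate).

The same workflow is available from the shell:

```bash
mlevent synth --seed 1 --documents 200 --out corpus/
mlevent validate corpus/
mlevent stats corpus/
mlevent train-ner corpus/ --dict corpus/lexicons/lexicon.tsv --out ner.pkl --seed 1
mlevent train-events corpus/ --out events.pkl --seed 1
mlevent evaluate-events corpus/test pred/
```

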