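"""Entity mention detection.

A single linear-chain sequence labeling model jointly predicts all 14
entity types over BIO-encoded tokens.  Features cover four families:
orthographic (shape, prefixes/suffixes), lexical (surface, lemma, ±2
context window), syntactic (POS, chunk) and dictionary matches (one
B/I-positioned flag per lexicon, from greedy longest matching).

The labeler is an averaged structured perceptron with Viterbi decoding —
the usual discriminative linear-chain model (emission weights per feature
and label, plus label-transition weights), trained by whole-sequence
updates and epoch-averaged for stability.  Training is deterministic given
the seed.

Two configurations mirror the standard experimental contrast: a *base*
model without lexicons and a *dictionary* model whose feature set adds
lexicon match flags.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AnnotatedDocument, Corpus, EntityMention, TextSpan
from .tokenize import Token, segment

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "NerConfig",
    "NerModel",
    "encode_bio",
    "decode_bio",
    "token_features",
    "lexicon_match",
    "train_ner",
    "predict_entities",
    "SequenceTagger",
]


# -- lexicons ------------------------------------------------------------


def _normalize(text: str) -> tuple[str, ...]:
    """Case-fold, collapse punctuation to spaces, split to tokens."""
    return tuple(re.sub(r"[^\w\s]", " ", text.casefold()).split())


@dataclass(frozen=True)
class Lexicon:
    """A semantic class with a set of normalized surface strings."""

    name: str
    entries: frozenset[tuple[str, ...]]

    @classmethod
    def from_surfaces(cls, name: str, surfaces) -> "Lexicon":
        entries = frozenset(n for n in map(_normalize, surfaces) if n)
        return cls(name, entries)

    @property
    def max_len(self) -> int:
        return max((len(e) for e in self.entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)


def read_lexicons(path: str | Path) -> dict[str, Lexicon]:
    """Read a ``<class>\\t<surface form>`` file into per-class lexicons."""
    by_class: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        cls_name, sep, surface = line.partition("\t")
        if not sep:
            raise ValueError(f"{path}:{line_no}: expected '<class>\\t<surface>'")
        by_class.setdefault(cls_name, []).append(surface)
    return {
        name: Lexicon.from_surfaces(name, surfaces)
        for name, surfaces in by_class.items()
    }


def write_lexicons(lexicons: dict[str, Lexicon], path: str | Path) -> None:
    lines = []
    for name in sorted(lexicons):
        for entry in sorted(lexicons[name].entries):
            lines.append(f"{name}\t{' '.join(entry)}")
    Path(path).write_text("".join(l + "\n" for l in lines), encoding="utf-8")


def lexicon_match(tokens: list[Token], lexicon: Lexicon) -> list[tuple[int, int]]:
    """Greedy leftmost-longest matching over normalized token forms.

    Tokens are expanded into their normalized subwords (hyphenated names
    contribute several), matched against the entries, and match boundaries
    mapped back to token indices.  Returns non-overlapping ``(start, end)``
    token index ranges (half-open).
    """
    owner: list[int] = []  # token index per subword
    words: list[str] = []
    for i, tok in enumerate(tokens):
        for w in _normalize(tok.surface):
            owner.append(i)
            words.append(w)
    matches: list[tuple[int, int]] = []
    i, n = 0, len(words)
    max_len = lexicon.max_len
    last_end = 0
    while i < n:
        for length in range(min(max_len, n - i), 0, -1):
            if tuple(words[i : i + length]) in lexicon.entries:
                start_tok, end_tok = owner[i], owner[i + length - 1] + 1
                if start_tok >= last_end:  # keep token ranges disjoint
                    matches.append((start_tok, end_tok))
                    last_end = end_tok
                i += length
                break
        else:
            i += 1
    return matches


# -- BIO encoding --------------------------------------------------------


def encode_bio(
    doc: AnnotatedDocument, sentences: list[list[Token]]
) -> list[list[str]]:
    """Per-sentence BIO label sequences for the document's entities.

    Entities are snapped outward to token boundaries.  Overlapping and
    nested entities are resolved by the longest-span rule (linear-chain
    labeling cannot express nesting); discards are logged.
    """
    labels = [["O"] * len(sent) for sent in sentences]
    order = sorted(
        doc.entities.values(), key=lambda e: (-len(e.span), e.span.start, e.id)
    )
    for ent in order:
        placed = False
        for s_idx, sent in enumerate(sentences):
            cover = [
                t_idx for t_idx, tok in enumerate(sent) if tok.span.overlaps(ent.span)
            ]
            if not cover:
                continue
            if any(labels[s_idx][t] != "O" for t in cover):
                logger.info(
                    "entity %s (%r) dropped from BIO encoding: overlaps a longer entity",
                    ent.id,
                    ent.surface,
                )
            else:
                snapped = (sent[cover[0]].span.start, sent[cover[-1]].span.end)
                if snapped != (ent.span.start, ent.span.end):
                    logger.info(
                        "entity %s snapped to token boundaries %s", ent.id, snapped
                    )
                labels[s_idx][cover[0]] = f"B-{ent.entity_type}"
                for t in cover[1:]:
                    labels[s_idx][t] = f"I-{ent.entity_type}"
            placed = True
            break
        if not placed:
            logger.warning("entity %s has no covering tokens", ent.id)
    return labels


def decode_bio(
    text: str, sentences: list[list[Token]], labels: list[list[str]]
) -> list[EntityMention]:
    """Recover entity mentions from BIO labels.

    Repair rule: an ``I-`` label without a matching open span is promoted
    to ``B-``.
    """
    entities: list[EntityMention] = []

    def close(etype: str, start_tok: Token, end_tok: Token) -> None:
        span = TextSpan(start_tok.span.start, end_tok.span.end)
        entities.append(
            EntityMention(
                f"T{len(entities) + 1}",
                etype,
                span,
                text[span.start : span.end],
            )
        )

    for sent, labs in zip(sentences, labels):
        open_type = None
        open_start = None
        prev_tok = None
        for tok, lab in zip(sent, labs):
            if lab == "O":
                tag, etype = "O", None
            else:
                tag, _, etype = lab.partition("-")
            if open_type is not None and (tag == "O" or tag == "B" or etype != open_type):
                close(open_type, open_start, prev_tok)
                open_type = None
            if tag in ("B", "I") and open_type is None:
                open_type, open_start = etype, tok
            prev_tok = tok
        if open_type is not None:
            close(open_type, open_start, prev_tok)
    return entities


# -- features ------------------------------------------------------------


def _shape(word: str) -> str:
    pattern = "".join(
        "X" if c.isupper() else "x" if c.islower() else "d" if c.isdigit() else c
        for c in word
    )
    return re.sub(r"(.)\1+", r"\1", pattern)  # collapse runs


def token_features(
    tokens: list[Token], lexicons: list[Lexicon] | None = None
) -> list[list[str]]:
    """Feature name lists per token for one sentence."""
    feats: list[list[str]] = []
    for i, tok in enumerate(tokens):
        w = tok.surface
        lw = w.lower()
        fs = [
            f"w={lw}",
            f"lemma={tok.lemma}",
            f"pos={tok.pos}",
            f"chunk={tok.chunk}",
            f"shape={_shape(w)}",
        ]
        if w.isupper() and len(w) > 1:
            fs.append("allcaps")
        if w[:1].isupper():
            fs.append("initcap")
        if any(c.isdigit() for c in w):
            fs.append("hasdigit")
        if "-" in w:
            fs.append("hashyphen")
        for k in (2, 3, 4):
            if len(lw) > k:
                fs.append(f"pre{k}={lw[:k]}")
                fs.append(f"suf{k}={lw[-k:]}")
        for off in (-2, -1, 1, 2):
            j = i + off
            if 0 <= j < len(tokens):
                fs.append(f"w[{off}]={tokens[j].surface.lower()}")
                fs.append(f"pos[{off}]={tokens[j].pos}")
            else:
                fs.append(f"w[{off}]=<pad>")
        if i > 0:
            fs.append(f"bigram={tokens[i - 1].surface.lower()}|{lw}")
        feats.append(fs)

    for lex in lexicons or ():
        for start, end in lexicon_match(tokens, lex):
            feats[start].append(f"dict[{lex.name}]=B")
            for j in range(start + 1, end):
                feats[j].append(f"dict[{lex.name}]=I")
    return feats


# -- the sequence labeler ------------------------------------------------


class SequenceTagger:
    """Averaged structured perceptron over linear label chains.

    Scores a label sequence as the sum of emission weights (active feature
    x label) and transition weights (previous label x label, with a
    distinguished start state); decodes with Viterbi.  Weights are averaged
    over epoch snapshots.
    """

    def __init__(self, epochs: int = 10, seed: int = 0):
        self.epochs = epochs
        self.seed = seed
        self.labels_: list[str] = []
        self.feature_index_: dict[str, int] = {}
        self.W_: np.ndarray | None = None  # (n_features, L)
        self.T_: np.ndarray | None = None  # (L + 1, L); row L = start

    # internal: map one sentence's features to index lists
    def _index(self, sent_feats, grow: bool) -> list[list[int]]:
        out = []
        for fs in sent_feats:
            idxs = []
            for f in fs:
                j = self.feature_index_.get(f)
                if j is None and grow:
                    j = self.feature_index_[f] = len(self.feature_index_)
                if j is not None:
                    idxs.append(j)
            out.append(idxs)
        return out

    def _viterbi(self, idx_sent: list[list[int]]) -> list[int]:
        L = len(self.labels_)
        n = len(idx_sent)
        E = np.empty((n, L))
        for i, idxs in enumerate(idx_sent):
            E[i] = self.W_[idxs].sum(axis=0) if idxs else 0.0
        delta = E[0] + self.T_[L]
        back = np.zeros((n, L), dtype=np.intp)
        trans = self.T_[:L]
        for i in range(1, n):
            scores = delta[:, None] + trans
            back[i] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + E[i]
        path = [int(delta.argmax())]
        for i in range(n - 1, 0, -1):
            path.append(int(back[i, path[-1]]))
        path.reverse()
        return path

    def fit(self, X, Y) -> "SequenceTagger":
        """X: sentences of feature-name lists; Y: parallel label sequences."""
        label_set = sorted({lab for sent in Y for lab in sent})
        self.labels_ = label_set
        label_index = {lab: i for i, lab in enumerate(label_set)}
        L = len(label_set)

        indexed = [self._index(sent, grow=True) for sent in X]
        gold = [[label_index[lab] for lab in sent] for sent in Y]

        n_feat = len(self.feature_index_)
        self.W_ = np.zeros((n_feat, L))
        self.T_ = np.zeros((L + 1, L))
        W_sum = np.zeros_like(self.W_)
        T_sum = np.zeros_like(self.T_)

        rng = np.random.default_rng(self.seed)
        order = np.arange(len(indexed))
        for _ in range(self.epochs):
            rng.shuffle(order)
            for s in order:
                idx_sent, g = indexed[s], gold[s]
                if not idx_sent:
                    continue
                pred = self._viterbi(idx_sent)
                if pred == g:
                    continue
                prev_g = prev_p = L
                for i, idxs in enumerate(idx_sent):
                    gi, pi = g[i], pred[i]
                    if gi != pi:
                        self.W_[idxs, gi] += 1.0
                        self.W_[idxs, pi] -= 1.0
                    if (prev_g, gi) != (prev_p, pi):
                        self.T_[prev_g, gi] += 1.0
                        self.T_[prev_p, pi] -= 1.0
                    prev_g, prev_p = gi, pi
            W_sum += self.W_
            T_sum += self.T_

        self.W_ = W_sum / self.epochs
        self.T_ = T_sum / self.epochs
        return self

    def predict(self, X) -> list[list[str]]:
        if self.W_ is None:
            raise RuntimeError("model is not trained")
        out = []
        for sent in X:
            if not sent:
                out.append([])
                continue
            idx_sent = self._index(sent, grow=False)
            out.append([self.labels_[i] for i in self._viterbi(idx_sent)])
        return out


# -- model wrapper -------------------------------------------------------


@dataclass
class NerConfig:
    epochs: int = 10
    train_splits: tuple[str, ...] = ("train", "devel")


@dataclass
class NerModel:
    tagger: SequenceTagger
    config: NerConfig
    lexicons: list[Lexicon] = field(default_factory=list)
    seed: int = 0

    @property
    def mode(self) -> str:
        return "dictionary" if self.lexicons else "base"


def train_ner(
    corpus: Corpus,
    config: NerConfig | None = None,
    lexicons: list[Lexicon] | None = None,
    seed: int = 0,
) -> NerModel:
    """Train the joint entity mention detector.

    With ``lexicons`` the model is the *dictionary* configuration; without,
    the *base* configuration.  Deterministic given the seed.
    """
    config = config or NerConfig()
    lexicons = list(lexicons or [])
    docs = list(corpus.documents(config.train_splits))
    if not docs:
        raise ValueError("empty training split")
    if not any(doc.entities for doc in docs):
        raise ValueError("training corpus contains no entity annotations")

    X, Y = [], []
    n_feat_tokens = 0
    for doc in docs:
        sentences = segment(doc.text)
        labels = encode_bio(doc, sentences)
        for sent, labs in zip(sentences, labels):
            X.append(token_features(sent, lexicons))
            Y.append(labs)
            n_feat_tokens += len(sent)
    tagger = SequenceTagger(epochs=config.epochs, seed=seed).fit(X, Y)
    logger.info(
        "trained %s NER model: %d sentences, %d tokens, %d features, %d labels",
        "dictionary" if lexicons else "base",
        len(X),
        n_feat_tokens,
        len(tagger.feature_index_),
        len(tagger.labels_),
    )
    return NerModel(tagger=tagger, config=config, lexicons=lexicons, seed=seed)


def predict_entities(model: NerModel, doc: AnnotatedDocument | str) -> list[EntityMention]:
    """Predict entity mentions for a document (or raw text)."""
    text = doc.text if isinstance(doc, AnnotatedDocument) else doc
    sentences = segment(text)
    X = [token_features(sent, model.lexicons) for sent in sentences]
    labels = model.tagger.predict(X)
    return decode_bio(text, sentences, labels)


def predict_document(
    model: NerModel, text: str, doc_id: str = "doc"
) -> AnnotatedDocument:
    doc = AnnotatedDocument(doc_id=doc_id, text=text)
    for ent in predict_entities(model, text):
        doc.entities[ent.id] = ent
    return doc
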