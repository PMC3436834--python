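"""Sentence splitting, tokenization and a rule-based shallow tagger.

The tagger interface is pluggable: anything with a
``tag(tokens) -> list[(lemma, pos, chunk)]`` method can replace the shipped
:class:`RuleTagger`, which covers the needs of feature extraction (coarse
POS, crude lemmatization, NP/VP chunking) without an external model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .model import TextSpan

__all__ = ["Token", "RuleTagger", "segment", "tokenize_sentence"]


@dataclass(frozen=True)
class Token:
    surface: str
    span: TextSpan
    lemma: str = ""
    pos: str = ""
    chunk: str = ""


# Abbreviations whose trailing period never ends a sentence.  Single capital
# letters ("E. coli", initials) are handled by rule.
ABBREVIATIONS = {
    "e.g.", "i.e.", "et", "al.", "etc.", "vs.", "cf.", "ca.", "approx.",
    "fig.", "figs.", "no.", "dr.", "spp.", "resp.",
}

_TOKEN_RE = re.compile(
    r"""
    \d+(?:\.\d+)+            # numbers with internal dots (doses, versions)
  | \w+(?:[-'/]\w+)*         # words, keeping internal hyphens/slashes
  | \S                       # any other single non-space character
    """,
    re.VERBOSE,
)


def tokenize_sentence(text: str, offset: int = 0) -> list[Token]:
    """Tokenize one sentence; spans index into the original document."""
    return [
        Token(m.group(), TextSpan(offset + m.start(), offset + m.end()))
        for m in _TOKEN_RE.finditer(text)
    ]


def _sentence_boundaries(text: str) -> list[tuple[int, int]]:
    """Half-open character ranges of sentences.

    A sentence ends at ``.``, ``!`` or ``?`` followed by whitespace, unless
    the period belongs to a known abbreviation or a single capital initial
    ("E. coli").
    """
    bounds: list[tuple[int, int]] = []
    start, i, n = 0, 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            if text[start:i].strip():
                bounds.append((start, i))
            start = i + 1
        elif ch in ".!?":
            nxt = i + 1
            while nxt < n and text[nxt] in ")\"']":
                nxt += 1
            after_space = nxt < n and text[nxt].isspace() and text[nxt] != "\n"
            end_of_text = nxt >= n
            if ch == "." and not end_of_text:
                # word carrying the period, e.g. "al." or the initial "E."
                w_start = i
                while w_start > 0 and not text[w_start - 1].isspace():
                    w_start -= 1
                word = text[w_start : i + 1]
                bare = word.lstrip("(\"'")
                if bare.lower() in ABBREVIATIONS or re.fullmatch(r"[A-Z]\.", bare):
                    i += 1
                    continue
            if end_of_text or after_space:
                if text[start:nxt].strip():
                    bounds.append((start, nxt))
                start = nxt
                i = nxt
                continue
        i += 1
    if text[start:].strip():
        bounds.append((start, n))
    return bounds


_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "its", "their", "our", "no"}
_PREPOSITIONS = {
    "of", "in", "on", "at", "by", "to", "from", "with", "into", "within",
    "through", "during", "after", "before", "between", "via", "using",
    "under", "over", "for",
}
_CONJUNCTIONS = {"and", "or", "but", "nor", "whereas", "while"}
_PRONOUNS = {"we", "it", "they", "he", "she", "i", "you", "who", "which"}
_AUX_VERBS = {
    "is", "are", "was", "were", "be", "been", "being", "has", "have", "had",
    "do", "does", "did", "may", "might", "can", "could", "will", "would",
    "shall", "should", "must", "appears", "appear", "seems", "seem",
    "remains", "remain", "not",
}
_COMMON_VERBS = {
    "show", "shows", "showed", "shown", "observe", "observed", "demonstrate",
    "demonstrated", "reveal", "revealed", "suggest", "suggests", "suggesting",
    "indicate", "indicated", "found", "find", "occur", "occurs", "occurred",
    "analysed", "analyzed", "examined", "detected", "measured", "grows",
    "fail", "failed", "undergo", "underwent", "lead", "leads", "led",
    "result", "results", "resulted",
}

#: POS tags treated as function words (never trigger candidates).
FUNCTION_POS = frozenset({"DT", "IN", "CC", "PRP", "MD", "AUX", "PUNCT", "TO"})


def _lemma(word: str, pos: str) -> str:
    w = word.lower()
    if pos.startswith("V"):
        for suf, rep in (("ies", "y"), ("ing", ""), ("ed", ""), ("es", "e"), ("s", "")):
            if w.endswith(suf) and len(w) > len(suf) + 2:
                return w[: -len(suf)] + rep
    elif pos.startswith("N"):
        if w.endswith("ies") and len(w) > 4:
            return w[:-3] + "y"
        if w.endswith("ses") or w.endswith("xes"):
            return w[:-2]
        if w.endswith("s") and not w.endswith("ss") and not w.endswith("us") and len(w) > 3:
            return w[:-1]
    return w


class RuleTagger:
    """Heuristic POS / lemma / chunk assignment.

    Coarse tagset: NN (nouns, default), VB (verbs), JJ (adjectives),
    RB (adverbs), CD (numbers), DT/IN/CC/PRP/MD/AUX/TO (function words),
    PUNCT.  Chunks: B-NP/I-NP over determiner–adjective–noun runs,
    B-VP/I-VP over verb runs, O elsewhere.
    """

    def tag(self, tokens: list[Token]) -> list[Token]:
        tagged: list[Token] = []
        for tok in tokens:
            w = tok.surface
            lw = w.lower()
            if not any(c.isalnum() for c in w):
                pos = "PUNCT"
            elif re.fullmatch(r"\d+(\.\d+)?", w):
                pos = "CD"
            elif lw in _DETERMINERS:
                pos = "DT"
            elif lw == "to":
                pos = "TO"
            elif lw in _PREPOSITIONS:
                pos = "IN"
            elif lw in _CONJUNCTIONS:
                pos = "CC"
            elif lw in _PRONOUNS:
                pos = "PRP"
            elif lw in _AUX_VERBS:
                pos = "AUX"
            elif lw in _COMMON_VERBS:
                pos = "VB"
            elif lw.endswith("ly"):
                pos = "RB"
            elif lw.endswith(("ed", "ing")) and len(lw) > 4:
                pos = "VBG" if lw.endswith("ing") else "VBD"
            elif lw.endswith(("es", "ates", "izes", "ises")) and len(lw) > 4:
                pos = "VBZ" if lw.endswith(("ates", "izes", "ises")) else "NN"
            elif lw.endswith(("al", "ous", "ive", "ic", "ary", "able")) and len(lw) > 4:
                pos = "JJ"
            else:
                pos = "NN"
            tagged.append(replace(tok, pos=pos, lemma=_lemma(w, pos)))

        # chunking over the tagged sequence
        out: list[Token] = []
        prev_chunk = "O"
        for tok in tagged:
            if tok.pos in {"DT", "JJ", "CD"} or tok.pos.startswith("N"):
                chunk = "I-NP" if prev_chunk.endswith("NP") else "B-NP"
            elif tok.pos.startswith("V") or tok.pos in {"AUX", "MD"}:
                chunk = "I-VP" if prev_chunk.endswith("VP") else "B-VP"
            else:
                chunk = "O"
            prev_chunk = chunk
            out.append(replace(tok, chunk=chunk))
        return out


_DEFAULT_TAGGER = RuleTagger()


def segment(text: str, tagger=None) -> list[list[Token]]:
    """Split text into sentences of tagged tokens.

    Token spans tile the non-whitespace text and index into ``text``.
    """
    tagger = tagger if tagger is not None else _DEFAULT_TAGGER
    sentences = []
    for start, end in _sentence_boundaries(text):
        tokens = tokenize_sentence(text[start:end], offset=start)
        if tokens:
            sentences.append(tagger.tag(tokens))
    return sentences
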