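"""N-gram word prediction over a normalized German-letter corpus.

The speller alphabet contains only A-Z, so the corpus is first
normalized: lowercased, the German graphemes ä/ö/ü/ß replaced by their
usual substitutions ae/oe/ue/ss, punctuation stripped.  A conditional
frequency distribution of unigrams, bigrams and trigrams (never crossing
sentence boundaries) scores completion candidates for the current
incomplete word: candidates matching the prefix are scored at the highest
n-gram order that has any match for the context (trigram on the last two
complete words, else bigram on the last word, else unigram), and a single
candidate is proposed only if its frequency strictly exceeds half the sum
of all candidate frequencies — at most one word can satisfy this.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

GRAPHEME_SUBSTITUTIONS = {"ä": "ae", "ö": "oe", "ü": "ue", "ß": "ss"}

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
_NON_LETTER = re.compile(r"[^a-z ]")


def normalize_text(text: str) -> list[list[str]]:
    """Normalize UTF-8 text into sentences of lowercase ascii word tokens.

    Sentences split on ./!/?; within a sentence, German graphemes are
    substituted (ä→ae, ö→oe, ü→ue, ß→ss), everything but letters becomes
    whitespace, and tokens are the remaining words.  Empty sentences are
    dropped.
    """
    sentences = []
    for raw in _SENTENCE_SPLIT.split(text):
        s = raw.lower()
        for src, dst in GRAPHEME_SUBSTITUTIONS.items():
            s = s.replace(src, dst)
        s = _NON_LETTER.sub(" ", s)
        tokens = s.split()
        if tokens:
            sentences.append(tokens)
    return sentences


def normalize_word(word: str) -> str:
    """Normalize a single word the same way the corpus is normalized."""
    s = word.lower()
    for src, dst in GRAPHEME_SUBSTITUTIONS.items():
        s = s.replace(src, dst)
    return _NON_LETTER.sub("", s)


@dataclass
class NGramModel:
    """Unigram/bigram/trigram frequency tables over a normalized corpus."""

    unigrams: dict[str, int] = field(default_factory=dict)
    bigrams: dict[tuple[str, str], int] = field(default_factory=dict)
    trigrams: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def vocabulary(self) -> set[str]:
        return set(self.unigrams)

    @property
    def token_count(self) -> int:
        return sum(self.unigrams.values())

    # -- serialization ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "unigrams": self.unigrams,
            "bigrams": {" ".join(k): v for k, v in self.bigrams.items()},
            "trigrams": {" ".join(k): v for k, v in self.trigrams.items()},
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False))

    @classmethod
    def from_json(cls, path: str | Path) -> "NGramModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            unigrams=dict(payload["unigrams"]),
            bigrams={tuple(k.split()): v for k, v in payload["bigrams"].items()},
            trigrams={tuple(k.split()): v for k, v in payload["trigrams"].items()},
        )


def build_model(sentences: list[list[str]]) -> NGramModel:
    """Count unigrams and within-sentence bigrams/trigrams."""
    if not sentences or not any(sentences):
        raise ValueError("corpus is empty")
    model = NGramModel()
    for sent in sentences:
        for i, w in enumerate(sent):
            model.unigrams[w] = model.unigrams.get(w, 0) + 1
            if i >= 1:
                bg = (sent[i - 1], w)
                model.bigrams[bg] = model.bigrams.get(bg, 0) + 1
            if i >= 2:
                tg = (sent[i - 2], sent[i - 1], w)
                model.trigrams[tg] = model.trigrams.get(tg, 0) + 1
    return model


def build_model_from_text(text: str) -> NGramModel:
    return build_model(normalize_text(text))


def build_model_from_file(path: str | Path) -> NGramModel:
    """Build from a plain-text UTF-8 corpus file (one or more sentences
    per line; lines starting with '#' are skipped)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    text = "\n".join(l for l in lines if not l.lstrip().startswith("#"))
    return build_model_from_text(text)


def default_corpus_model() -> NGramModel:
    """Model over the small bundled synthetic German corpus."""
    return build_model_from_file(Path(__file__).parent / "data" /
                                 "synthetic_corpus_de.txt")


def candidate_words(model: NGramModel, context: tuple[str, ...],
                    prefix: str = "") -> dict[str, int]:
    """Frequencies of vocabulary words starting with ``prefix``, scored at
    the highest n-gram order with any contextual match.

    ``context`` holds up to the last two *complete* words before the
    prefix (earlier word first).  Backoff is strict: if any trigram
    (w1, w2, cand) matches, only trigram counts are returned; else if any
    bigram (w2, cand) matches, only bigram counts; else unigram counts.
    Orders are never mixed.  An empty prefix considers all words.
    """
    prefix = normalize_word(prefix)
    context = tuple(normalize_word(w) for w in context if w)

    if len(context) >= 2:
        w1, w2 = context[-2], context[-1]
        tri = {
            k[2]: v for k, v in model.trigrams.items()
            if k[0] == w1 and k[1] == w2 and k[2].startswith(prefix)
        }
        if tri:
            return tri
    if len(context) >= 1:
        w2 = context[-1]
        bi = {
            k[1]: v for k, v in model.bigrams.items()
            if k[0] == w2 and k[1].startswith(prefix)
        }
        if bi:
            return bi
    return {w: c for w, c in model.unigrams.items() if w.startswith(prefix)}


def probable_word(candidates: dict[str, int]) -> str | None:
    """The unique candidate whose frequency strictly exceeds half the sum
    of all candidate frequencies, or None.

    At most one word can pass: two would jointly exceed the total.
    """
    if not candidates:
        return None
    if any(v < 0 for v in candidates.values()):
        raise ValueError("frequencies must be >= 0")
    total = sum(candidates.values())
    for word, freq in candidates.items():
        if freq > total / 2:
            return word
    return None


def propose(model: NGramModel, current_string: str) -> str | None:
    """Full prediction step for the speller's current string.

    Splits the (uppercase, space-separated) string into complete words
    and the trailing incomplete prefix, queries the candidate set and
    applies the half-sum threshold.  Returns the proposed word in
    uppercase, or None.  A proposal identical to the already-typed prefix
    is still returned (accepting it completes the word with its trailing
    space).
    """
    parts = current_string.split(" ")
    prefix = parts[-1]
    complete = [p for p in parts[:-1] if p]
    context = tuple(complete[-2:])
    cands = candidate_words(model, context, prefix)
    word = probable_word(cands)
    return word.upper() if word is not None else None
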