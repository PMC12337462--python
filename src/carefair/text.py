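"""Deterministic text utilities: normalisation, tokenisation, sentence
splitting and dictionary-guided lemmatisation.

All linguistic resources (stop words, dictionary snapshot, verb list) are
shipped as versioned data files so that validation and vocabulary building
are bit-stable across machines.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache
from importlib import resources

__all__ = [
    "normalize_text",
    "tokenize",
    "word_count",
    "split_sentences",
    "load_wordlist",
    "load_stopwords",
    "load_dictionary",
    "Lemmatizer",
    "default_lemmatizer",
]

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:\.\d+)?")
# sentence boundary: terminal punctuation followed by whitespace and an
# upper-case letter or digit; common titles/abbreviations are protected
_ABBREV = ("Mr", "Mrs", "Ms", "Dr", "Prof", "St", "e.g", "i.e", "etc", "approx")
_SENT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9\"'(])")


def normalize_text(text: str) -> str:
    """NFKC-normalise and collapse runs of whitespace to single spaces."""
    text = unicodedata.normalize("NFKC", text)
    return re.sub(r"\s+", " ", text).strip()


def tokenize(text: str, lowercase: bool = False) -> list[str]:
    """Split on word characters; punctuation is discarded."""
    toks = _TOKEN_RE.findall(text)
    return [t.lower() for t in toks] if lowercase else toks


def word_count(text: str) -> int:
    """Whitespace token count after normalisation (the 200/500-word filter
    counter)."""
    norm = normalize_text(text)
    return len(norm.split()) if norm else 0


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitter protecting common title abbreviations."""
    norm = normalize_text(text)
    if not norm:
        return []
    # shield "Mr. Smith"-style abbreviations from the boundary regex
    shielded = norm
    for abbr in _ABBREV:
        shielded = re.sub(rf"\b{re.escape(abbr)}\.", abbr.replace(".", "\x00") + "\x00", shielded)
    parts = _SENT_RE.split(shielded)
    return [p.replace("\x00", ".").strip() for p in parts if p.strip()]


def _read_data(name: str) -> str:
    return resources.files("carefair.data").joinpath(name).read_text(encoding="utf-8")


def load_wordlist(name: str) -> list[str]:
    """Load a one-term-per-line data file, skipping comments and blanks."""
    out = []
    for line in _read_data(name).splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@lru_cache(maxsize=None)
def load_stopwords() -> frozenset[str]:
    return frozenset(load_wordlist("stopwords.txt"))


@lru_cache(maxsize=None)
def load_dictionary() -> frozenset[str]:
    return frozenset(load_wordlist("dictionary.txt"))


@lru_cache(maxsize=None)
def load_verbs() -> frozenset[str]:
    return frozenset(load_wordlist("verbs.txt"))


class Lemmatizer:
    """Suffix-stripping lemmatiser guided by the shipped dictionary.

    Candidate reductions (plural -s/-es/-ies, participial -ing/-ed with
    e-restoration and consonant undoubling) are accepted only when the
    candidate is a dictionary word; otherwise the token is returned
    unchanged. This keeps behaviour stable and auditable: "walking" and
    "walked" reduce to "walk", "dementias" to "dementia", while "demented"
    stays distinct from "dementia".
    """

    _EXCEPTIONS = {
        "men": "man",
        "women": "woman",
        "children": "child",
        "people": "people",
        "feet": "foot",
        "teeth": "tooth",
        "fell": "fall",
        "falls": "fall",
        "fallen": "fall",
        "needs": "need",
        "left": "leave",
        "said": "say",
        "worse": "bad",
        "better": "good",
    }

    def __init__(self, dictionary: frozenset[str] | None = None):
        self.dictionary = dictionary if dictionary is not None else load_dictionary()

    def _candidates(self, w: str) -> list[str]:
        cands: list[str] = []
        if len(w) > 3 and w.endswith("ies"):
            cands.append(w[:-3] + "y")
        if len(w) > 4 and w.endswith("es") and w[-3] in "sxz" or w.endswith(("ches", "shes")):
            cands.append(w[:-2])
        if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
            cands.append(w[:-1])
        for suf in ("ing", "ed"):
            if len(w) >= len(suf) + 2 and w.endswith(suf):
                stem = w[: -len(suf)]
                cands.append(stem)
                cands.append(stem + "e")
                if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "ls":
                    cands.append(stem[:-1])
        return cands

    def lemma(self, token: str) -> str:
        w = token.lower()
        if w in self._EXCEPTIONS:
            return self._EXCEPTIONS[w]
        if w in self.dictionary:
            return w
        for cand in self._candidates(w):
            if cand in self.dictionary:
                return cand
        return w

    def lemmas(self, text: str) -> list[str]:
        return [self.lemma(t) for t in tokenize(text, lowercase=True)]

    def is_dictionary_word(self, lemma: str) -> bool:
        return lemma in self.dictionary


@lru_cache(maxsize=1)
def default_lemmatizer() -> Lemmatizer:
    return Lemmatizer()
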