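"""Corpus preparation: eligibility filtering, near-duplicate removal,
rule-based gender swapping and counterfactual-pair validation.

The unit of analysis downstream is a counterfactual pair: two versions of
the same care note that are identical except for gendered tokens. A pair is
only *validated* when both versions have the same number of sentences and,
sentence by sentence, the same count of non-stop-word, non-gendered tokens —
so any downstream difference between summaries of the two versions is
attributable to the summariser, not the inputs.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .text import (
    load_stopwords,
    load_verbs,
    normalize_text,
    split_sentences,
    tokenize,
    word_count,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CareDocument",
    "CounterfactualPair",
    "FilterReport",
    "GenderLexicon",
    "DEFAULT_EXCLUSION_TERMS",
    "filter_eligible",
    "dedupe_near",
    "swap_gender",
    "validate_pair",
    "make_pair",
    "read_corpus",
    "write_pairs",
    "read_pairs",
]

# screening examples of situations that do not transfer across a gender swap:
# sex-specific anatomy/procedures and domestic violence. Configurable.
DEFAULT_EXCLUSION_TERMS = (
    "mastectomy",
    "hysterectomy",
    "prostate",
    "cervical",
    "ovarian",
    "testicular",
    "pregnancy",
    "pregnant",
    "menopause",
    "domestic violence",
    "domestic abuse",
)


@dataclass
class CareDocument:
    doc_id: str
    text: str
    gender_original: str = "female"
    age: float | None = None
    ethnicity: str | None = None


@dataclass
class CounterfactualPair:
    doc_id: str
    female_text: str
    male_text: str
    validated: bool = False
    validation_detail: dict = field(default_factory=dict)

    def text_for(self, gender: str) -> str:
        if gender == "female":
            return self.female_text
        if gender == "male":
            return self.male_text
        raise ValueError(f"unknown gender {gender!r}")


@dataclass
class FilterReport:
    n_input: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_excluded_terms: int = 0
    n_near_duplicate: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def filter_eligible(
    corpus: Sequence[CareDocument],
    min_words: int = 200,
    max_words: int = 500,
    exclusion_terms: Iterable[str] = DEFAULT_EXCLUSION_TERMS,
) -> tuple[list[CareDocument], FilterReport]:
    """Keep documents with min_words <= length <= max_words containing no
    exclusion term. Each document lands in exactly one report bucket,
    evaluated in order: too short, too long, excluded term, kept."""
    if min_words > max_words:
        raise ValueError("min_words must be <= max_words")
    terms = [t.lower() for t in exclusion_terms]
    report = FilterReport(n_input=len(corpus))
    kept: list[CareDocument] = []
    for doc in corpus:
        if doc.text is None or not normalize_text(doc.text):
            raise ValueError(f"document {doc.doc_id!r} has no text")
        n = word_count(doc.text)
        if n < min_words:
            report.n_too_short += 1
        elif n > max_words:
            report.n_too_long += 1
        elif _contains_term(doc.text, terms):
            report.n_excluded_terms += 1
        else:
            kept.append(doc)
    report.n_kept = len(kept)
    return kept, report


def _contains_term(text: str, terms: Sequence[str]) -> bool:
    toks = tokenize(text, lowercase=True)
    joined = " " + " ".join(toks) + " "
    return any(f" {t} " in joined for t in terms)


def _shingles(tokens: Sequence[str], k: int) -> frozenset[tuple[str, ...]]:
    if len(tokens) < k:
        return frozenset({tuple(tokens)})
    return frozenset(tuple(tokens[i : i + k]) for i in range(len(tokens) - k + 1))


def dedupe_near(
    corpus: Sequence[CareDocument],
    shingle_size: int = 5,
    jaccard_threshold: float = 0.9,
) -> list[CareDocument]:
    """Remove near-duplicates by word-shingle Jaccard similarity, keeping the
    earlier document in input order."""
    if shingle_size < 1:
        raise ValueError("shingle_size must be >= 1")
    if not (0 < jaccard_threshold <= 1):
        raise ValueError("jaccard_threshold must be in (0, 1]")
    kept: list[CareDocument] = []
    kept_shingles: list[frozenset] = []
    for doc in corpus:
        toks = tokenize(doc.text, lowercase=True)
        if len(toks) < shingle_size:
            logger.warning("document %s shorter than shingle size; using whole text", doc.doc_id)
        sh = _shingles(toks, shingle_size)
        dup = False
        for other in kept_shingles:
            union = len(sh | other)
            if union and len(sh & other) / union >= jaccard_threshold:
                dup = True
                break
        if dup:
            continue
        kept.append(doc)
        kept_shingles.append(sh)
    return kept


class GenderLexicon:
    """Bidirectional gendered-token mapping with case preservation.

    Ambiguous "her" is resolved by local context: "her" + verb/function word
    (or end of clause) is the objective pronoun -> "him"; "her" + content
    word is the possessive determiner -> "his". The reverse m2f direction
    maps both "his" and "him" to "her" (the Ms/Mrs collapse and the
    his->her/hers collapse are logged as lossy).
    """

    #: function words that start a new phrase after an objective "her"
    _OBJ_NEXT = frozenset(
        "the a an to and or but if when because about after before that this "
        "these those there then at on in with from by for of not so as "
        "i you we they he she it is was are were be been being will would "
        "can could should may might must do does did have has had".split()
    )

    def __init__(self, rows: Sequence[tuple[str, str, str]], mr_maps_to: str = "mrs"):
        self.rows = list(rows)
        self.f2m: dict[str, str] = {}
        self.m2f: dict[str, str] = {}
        for female, male, kind in self.rows:
            female, male = female.lower(), male.lower()
            if kind == "pos_disambiguated":
                continue  # handled contextually
            self.f2m.setdefault(female, male)
            self.m2f.setdefault(male, female)
        # ambiguous forms
        self.f2m.pop("her", None)
        self.m2f["his"] = "her"
        self.m2f["him"] = "her"
        self.m2f["mr"] = mr_maps_to
        self._verbs = load_verbs()

    @classmethod
    def from_tsv(cls, path: str | Path | None = None, **kw) -> "GenderLexicon":
        if path is None:
            content = resources.files("carefair.data").joinpath("gender_lexicon.tsv").read_text()
        else:
            content = Path(path).read_text(encoding="utf-8")
        reader = csv.reader(io.StringIO(content), delimiter="\t")
        rows = []
        for i, row in enumerate(reader):
            if i == 0 and row and row[0].lower() == "female_form":
                continue
            if len(row) >= 3:
                rows.append((row[0], row[1], row[2]))
        return cls(rows, **kw)

    def gendered_tokens(self) -> frozenset[str]:
        toks = {"her", "him", "his", "hers"}
        for f, m, _ in self.rows:
            toks.add(f.lower())
            toks.add(m.lower())
        return frozenset(toks)

    def is_gendered(self, token: str) -> bool:
        return token.lower() in self.gendered_tokens()

    # -- swapping -----------------------------------------------------------

    @staticmethod
    def _match_case(template: str, repl: str) -> str:
        if template.isupper():
            return repl.upper()
        if template[:1].isupper():
            return repl.capitalize()
        return repl

    def _resolve_her(self, next_token: str | None) -> str:
        if next_token is None:
            return "him"
        nt = next_token.lower()
        if nt in self._OBJ_NEXT or nt in self._verbs:
            return "him"
        return "his"

    def swap(self, text: str, direction: str) -> str:
        if direction not in ("f2m", "m2f"):
            raise ValueError("direction must be 'f2m' or 'm2f'")
        mapping = self.f2m if direction == "f2m" else self.m2f
        import re as _re

        token_re = _re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?")
        matches = list(token_re.finditer(text))
        out = []
        last = 0
        for i, m in enumerate(matches):
            tok = m.group(0)
            low = tok.lower()
            repl = None
            if direction == "f2m" and low == "her":
                # objective if followed by punctuation (gap contains non-space)
                nxt = None
                if i + 1 < len(matches):
                    gap = text[m.end() : matches[i + 1].start()]
                    nxt = None if any(c in gap for c in ".,;:!?") else matches[i + 1].group(0)
                repl = self._resolve_her(nxt)
            elif low in mapping:
                repl = mapping[low]
            if repl is not None:
                out.append(text[last : m.start()])
                out.append(self._match_case(tok, repl))
                last = m.end()
        out.append(text[last:])
        return "".join(out)


def swap_gender(text: str, lexicon: GenderLexicon | None = None, direction: str = "f2m") -> str:
    """Replace every lexicon-covered gendered token by its counterpart,
    preserving case; all other bytes pass through unchanged."""
    lex = lexicon if lexicon is not None else GenderLexicon.from_tsv()
    return lex.swap(text, direction)


def validate_pair(
    pair: CounterfactualPair, lexicon: GenderLexicon | None = None
) -> CounterfactualPair:
    """Set the validated flag: equal sentence counts and, per aligned
    sentence, equal counts of non-stop-word non-gendered tokens."""
    lex = lexicon if lexicon is not None else GenderLexicon.from_tsv()
    if not pair.female_text.strip() or not pair.male_text.strip():
        raise ValueError(f"pair {pair.doc_id!r} has an empty version")
    stop = load_stopwords()
    gendered = lex.gendered_tokens()
    f_sents = split_sentences(pair.female_text)
    m_sents = split_sentences(pair.male_text)
    if len(f_sents) != len(m_sents):
        pair.validated = False
        pair.validation_detail = {
            "mismatch": "sentence_count",
            "female_sentences": len(f_sents),
            "male_sentences": len(m_sents),
        }
        return pair
    for idx, (fs, ms) in enumerate(zip(f_sents, m_sents)):
        fc = sum(1 for t in tokenize(fs, lowercase=True) if t not in stop and t not in gendered)
        mc = sum(1 for t in tokenize(ms, lowercase=True) if t not in stop and t not in gendered)
        if fc != mc:
            pair.validated = False
            pair.validation_detail = {
                "mismatch": "word_count",
                "sentence_index": idx,
                "female_count": fc,
                "male_count": mc,
            }
            return pair
    pair.validated = True
    pair.validation_detail = {"mismatch": None, "n_sentences": len(f_sents)}
    return pair


def make_pair(
    doc: CareDocument, lexicon: GenderLexicon | None = None
) -> CounterfactualPair:
    """Build a counterfactual pair from a document by swapping its gender,
    then validate it."""
    lex = lexicon if lexicon is not None else GenderLexicon.from_tsv()
    if doc.gender_original == "female":
        pair = CounterfactualPair(doc.doc_id, doc.text, lex.swap(doc.text, "f2m"))
    elif doc.gender_original == "male":
        pair = CounterfactualPair(doc.doc_id, lex.swap(doc.text, "m2f"), doc.text)
    else:
        raise ValueError(
            f"document {doc.doc_id!r}: gender {doc.gender_original!r} is not swapped "
            "(non-binary markers are flagged, not swapped)"
        )
    return validate_pair(pair, lex)


# -- IO ----------------------------------------------------------------------

def read_corpus(path: str | Path) -> list[CareDocument]:
    """Read a corpus from CSV or JSONL (doc_id, text, gender[, age, ethnicity])."""
    path = Path(path)
    docs: list[CareDocument] = []
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                docs.append(_doc_from_record(row))
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    docs.append(_doc_from_record(json.loads(line)))
    seen = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r}")
        seen.add(d.doc_id)
    return docs


def _doc_from_record(rec: dict) -> CareDocument:
    if "text" not in rec or rec["text"] in (None, ""):
        raise ValueError(f"document {rec.get('doc_id')!r} is missing text")
    age = rec.get("age")
    return CareDocument(
        doc_id=str(rec["doc_id"]),
        text=rec["text"],
        gender_original=str(rec.get("gender", rec.get("gender_original", "female"))).lower(),
        age=float(age) if age not in (None, "") else None,
        ethnicity=rec.get("ethnicity") or None,
    )


def write_pairs(pairs: Iterable[CounterfactualPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(json.dumps(asdict(p)) + "\n")


def read_pairs(path: str | Path) -> list[CounterfactualPair]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                pairs.append(CounterfactualPair(**json.loads(line)))
    return pairs
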