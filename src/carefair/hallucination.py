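"""Hallucination audit: medical terms present in a summary but absent from
its source text.

Matching is lemma-level with word boundaries (never substring), so
"dementias" matches the term "dementia" but "demented" does not. Negation is
not parsed ("no history of dementia" counts as present in the source) —
a documented limitation of the plain term scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus import CounterfactualPair
from .harness import SummaryRecord
from .text import Lemmatizer, default_lemmatizer, load_wordlist

__all__ = [
    "HallucinationRecord",
    "load_medical_terms",
    "scan_terms",
    "audit",
    "opportunity_count",
]


@dataclass
class HallucinationRecord:
    doc_id: str
    gender: str
    model: str
    max_tokens_level: str
    term: str
    in_source: bool
    in_summary: bool

    @property
    def hallucinated(self) -> bool:
        return self.in_summary and not self.in_source


def load_medical_terms(path: str | Path | None = None) -> list[str]:
    """One lemma per line; default is the shipped starter list of common
    long-term-care diagnoses."""
    if path is None:
        return load_wordlist("medical_terms.txt")
    terms = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms


def scan_terms(
    text: str, terms: Sequence[str], lemmatizer: Lemmatizer | None = None
) -> set[str]:
    """Terms whose lemma occurs among the text's lemmas (word-boundary,
    case-insensitive)."""
    if not terms:
        return set()
    lem = lemmatizer or default_lemmatizer()
    lemmas = set(lem.lemmas(text))
    return {t for t in terms if lem.lemma(t) in lemmas}


def audit(
    pairs: Sequence[CounterfactualPair],
    summaries: Sequence[SummaryRecord],
    terms: Sequence[str] | None = None,
    lemmatizer: Lemmatizer | None = None,
) -> tuple[list[HallucinationRecord], pd.DataFrame]:
    """One record per (summary, term); aggregate hallucination counts by
    gender and model."""
    term_list = list(terms) if terms is not None else load_medical_terms()
    lem = lemmatizer or default_lemmatizer()
    by_id = {p.doc_id: p for p in pairs}
    source_cache: dict[tuple[str, str], set[str]] = {}
    records: list[HallucinationRecord] = []
    for rec in summaries:
        if rec.doc_id not in by_id:
            raise ValueError(f"summary for unknown doc_id {rec.doc_id!r} (no source pair)")
        skey = (rec.doc_id, rec.gender)
        if skey not in source_cache:
            source_cache[skey] = scan_terms(by_id[rec.doc_id].text_for(rec.gender), term_list, lem)
        in_source = source_cache[skey]
        in_summary = scan_terms(rec.summary_text, term_list, lem)
        for t in term_list:
            records.append(
                HallucinationRecord(
                    rec.doc_id, rec.gender, rec.model_name, rec.max_tokens_level,
                    t, t in in_source, t in in_summary,
                )
            )
    rows = []
    for (g, m), grp in _groupby_gender_model(records):
        rows.append({"gender": g, "model": m, "n_hallucinated": sum(r.hallucinated for r in grp)})
    counts = pd.DataFrame(rows)
    if counts.empty:
        counts = pd.DataFrame(columns=["gender", "model", "n_hallucinated"])
    return records, counts


def _groupby_gender_model(records):
    keys = sorted({(r.gender, r.model) for r in records})
    for k in keys:
        yield k, [r for r in records if (r.gender, r.model) == k]


def opportunity_count(n_docs: int, n_versions: int, n_param_sets: int, n_terms: int) -> int:
    """Size of the hallucination opportunity space: documents x gender
    versions x (model, max-tokens) parameter sets x terms checked."""
    args = (n_docs, n_versions, n_param_sets, n_terms)
    if any((not isinstance(a, (int,)) and not float(a).is_integer()) or a <= 0 for a in args):
        raise ValueError("all arguments must be positive integers")
    return int(n_docs) * int(n_versions) * int(n_param_sets) * int(n_terms)
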