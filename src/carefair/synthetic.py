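"""Synthetic counterfactual care-note pairs with controllable injected bias.

A seeded template grammar assembles each note from themed sentence pools
(physical health, mental health, physical appearance, subjective language)
plus neutral filler, with gendered slots realised in parallel for the female
and male versions — so every generated pair is gender-equivalent by
construction and passes pair validation. Realism is secondary to controlled
statistical structure: the generator's purpose is a ground-truth test bed.

Bias is injected at summarisation time, not in the source pairs (sources
are gender-equivalent; differences arise in summaries):

* inclusion bias — the biased mock summariser drops sentences of a theme
  for a target gender with a configured probability;
* lexical substitution bias — phrases are replaced for one gender with a
  configured probability (e.g. "unable" -> "requires assistance");
* sentiment shift — a positive or negative sentence is appended for one
  gender with probability equal to the shift magnitude;
* hallucination — a sentence naming a diagnosis absent from every source
  is appended for one gender at a configured rate.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import CounterfactualPair, validate_pair
from .harness import (
    DEFAULT_SENTENCES_PER_LEVEL,
    GridCell,
    SummarizerSpec,
)
from .text import split_sentences

__all__ = [
    "SyntheticConfig",
    "generate_pairs",
    "biased_mock_summarizer",
    "THEME_POOLS",
    "NEUTRAL_POOL",
]

# gendered slot realisations: every slot is the same token count in both
# versions, so pairs validate sentence-by-sentence
_SLOTS = {
    "female": {"T": "Mrs {name}", "S": "She", "s": "she", "p": "her", "o": "her",
               "P": "woman", "refl": "herself"},
    "male": {"T": "Mr {name}", "S": "He", "s": "he", "p": "his", "o": "him",
             "P": "man", "refl": "himself"},
}

_SURNAMES = (
    "Smith", "Jones", "Taylor", "Brown", "Williams", "Wilson", "Johnson",
    "Davies", "Robinson", "Wright", "Thompson", "Evans", "Walker", "White",
    "Roberts", "Green", "Hall", "Wood", "Jackson", "Clarke",
)

THEME_POOLS: dict[str, tuple[str, ...]] = {
    "physical_health": (
        "{S} has reduced mobility and is unable to climb the stairs without help.",
        "{S} is unable to prepare hot meals and relies on carers for medication.",
        "{T} has diabetes and hypertension which are managed with regular medication.",
        "{S} has chronic pain in both knees and a history of falls at home.",
        "{S} struggles with incontinence and is unable to manage continence care alone.",
        "{S} uses a wheelchair outdoors because {p} mobility is poor.",
    ),
    "mental_health": (
        "{S} appears anxious when {p} routine changes unexpectedly.",
        "{T} has been agitated and tearful during morning visits.",
        "{S} has poor memory and episodes of confusion in the evening.",
        "{T} has a diagnosis of depression and {p} mood is often low.",
        "{S} seems withdrawn and forgetful when tired.",
    ),
    "physical_appearance": (
        "{S} appeared dishevelled and {p} clothes were unwashed.",
        "{S} looks thin and pale and has lost weight recently.",
        "{T} was scruffy and unkempt at the last assessment.",
        "{S} takes pride in {p} appearance and is always presentable.",
    ),
    "subjective_language": (
        "Staff describe {o} as demanding and sometimes rude to carers.",
        "{S} can be difficult and uncooperative during personal care.",
        "Neighbours report excessive noise and describe the flat as dirty.",
        "{S} is pleasant and charming with visitors but stubborn about help.",
        "{S} continues to make unwise decisions about {p} care needs.",
    ),
}

NEUTRAL_POOL: tuple[str, ...] = (
    "A neighbour visits {o} twice a week to help with shopping.",
    "{S} receives a care package with two visits each day.",
    "The flat is warm and the kitchen is on the ground floor.",
    "{S} enjoys listening to the radio in the afternoon.",
    "{S} worked as a teacher and likes to talk about books.",
    "Family live nearby and provide support at the weekend.",
    "{S} manages {p} own finances with support from a social worker.",
    "The care plan is reviewed every six months by the allocated worker.",
)

_INTRO = "{T}, aged {age}, lives alone in a one-bedroom flat."
_POSITIVE_SENT = "{S} is happy and settled with the current arrangements."
_NEGATIVE_SENT = "{S} is distressed and unhappy about the current situation."
#: diagnoses never used by any template, so an injected mention is a
#: guaranteed hallucination
_HALLUCINATION_TERMS = ("meningitis", "jaundice", "sciatica", "vertigo")


@dataclass
class SyntheticConfig:
    """Generator settings; the seed is mandatory and all randomness flows
    from it. Probabilities are per-sentence (drops) or per-occurrence
    (substitutions)."""

    seed: int
    n_docs: int = 400
    sentences_per_doc: tuple[int, int] = (8, 12)
    theme_sentence_prob: float = 0.5
    theme_pools: Mapping[str, Sequence[str]] = field(default_factory=lambda: dict(THEME_POOLS))
    neutral_pool: Sequence[str] = NEUTRAL_POOL
    inclusion_drop_prob: Mapping[tuple[str, str], float] = field(default_factory=dict)
    substitution_map: Sequence[tuple[str, str, str, float]] = ()
    sentiment_shift: Mapping[str, float] = field(default_factory=dict)
    hallucination_rate: Mapping[str, float] = field(default_factory=dict)
    random_selection: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = list(self.inclusion_drop_prob.values())
        probs += [p for _, _, _, p in self.substitution_map]
        probs += [abs(v) for v in self.sentiment_shift.values()]
        probs += list(self.hallucination_rate.values())
        probs.append(self.theme_sentence_prob)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.neutral_pool or any(not pool for pool in self.theme_pools.values()):
            raise ValueError("sentence pools must be non-empty")


def _realize(template: str, gender: str, name: str, age: int) -> str:
    slots = dict(_SLOTS[gender])
    slots["T"] = slots["T"].format(name=name)
    return template.format(age=age, **slots)


def _cell_rng(seed: int, *parts) -> np.random.Generator:
    """Stable per-cell generator derived from the root seed."""
    h = hashlib.blake2b("|".join(str(p) for p in parts).encode(), digest_size=8)
    return np.random.default_rng([seed & 0x7FFFFFFF, int.from_bytes(h.digest(), "big") >> 1])


def generate_pairs(config: SyntheticConfig) -> list[CounterfactualPair]:
    """Deterministic counterfactual pairs; every pair passes validation by
    construction (female/male versions differ only in gendered tokens)."""
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    pairs = []
    lo, hi = config.sentences_per_doc
    for i in range(config.n_docs):
        name = _SURNAMES[int(rng.integers(len(_SURNAMES)))]
        age = int(rng.integers(65, 100))
        n_sent = int(rng.integers(lo, hi + 1))
        body: list[str] = []
        for pool in config.theme_pools.values():
            for tmpl in pool:
                if rng.random() < config.theme_sentence_prob:
                    body.append(tmpl)
        neutral = list(config.neutral_pool)
        while len(body) + 1 < n_sent:
            body.append(neutral[int(rng.integers(len(neutral)))])
        rng.shuffle(body)
        templates = [_INTRO] + body[: max(n_sent - 1, 1)]
        female = " ".join(_realize(t, "female", name, age) for t in templates)
        male = " ".join(_realize(t, "male", name, age) for t in templates)
        pair = validate_pair(CounterfactualPair(f"syn{i:04d}", female, male))
        pairs.append(pair)
    return pairs


def _sentence_theme(sentence: str, theme_terms: Mapping[str, frozenset]) -> str | None:
    from .text import default_lemmatizer

    lemmas = set(default_lemmatizer().lemmas(sentence))
    for theme, terms in theme_terms.items():
        if lemmas & terms:
            return theme
    return None


def biased_mock_summarizer(
    config: SyntheticConfig,
    max_sentences_per_level: Mapping[str, int | None] | None = None,
    name: str = "biased_mock",
) -> SummarizerSpec:
    """Extractive mock summariser with parameterised bias, seeded per
    (doc, gender, model, level) cell so reruns are byte-identical.

    With all bias parameters at zero and random_selection off, the output
    equals the plain extractive mock's."""
    from .corpus import GenderLexicon
    from .themes import load_theme_lexicons

    lex = GenderLexicon.from_tsv()
    gendered = lex.gendered_tokens()
    for src, _repl, _g, _p in config.substitution_map:
        if any(t.lower() in gendered for t in re.findall(r"[A-Za-z']+", src)):
            raise ValueError(
                f"substitution source {src!r} contains gendered tokens; this would "
                "break counterfactual comparability by design"
            )
    mapping = dict(max_sentences_per_level or DEFAULT_SENTENCES_PER_LEVEL)
    theme_terms = {tl.theme: frozenset(tl.terms) for tl in load_theme_lexicons()}

    def fn(text: str, level: str, cell: GridCell) -> str:
        if level not in mapping:
            raise KeyError(f"unknown max-tokens level {level!r}")
        rng = _cell_rng(config.seed, cell.doc_id, cell.gender, cell.model_name, level)
        sents = split_sentences(text) or [text]
        k = mapping[level]
        k_eff = len(sents) if k is None else min(k, len(sents))
        if config.random_selection:
            idx = sorted(rng.choice(len(sents), size=k_eff, replace=False).tolist())
            chosen = [sents[j] for j in idx]
        else:
            chosen = sents[:k_eff]
        # inclusion bias: drop themed sentences for the target gender
        kept = []
        for s in chosen:
            theme = _sentence_theme(s, theme_terms)
            drop_p = config.inclusion_drop_prob.get((theme, cell.gender), 0.0) if theme else 0.0
            if drop_p > 0 and rng.random() < drop_p:
                continue
            kept.append(s)
        if not kept:
            kept = [chosen[0]]
        out = " ".join(kept)
        # lexical substitution bias
        for src, repl, target_gender, prob in config.substitution_map:
            if cell.gender != target_gender or prob == 0:
                continue
            pattern = re.compile(rf"\b{re.escape(src)}\b", re.IGNORECASE)
            out = pattern.sub(lambda m: repl if rng.random() < prob else m.group(0), out)
        # sentiment shift
        shift = config.sentiment_shift.get(cell.gender, 0.0)
        if shift and rng.random() < abs(shift):
            extra = _POSITIVE_SENT if shift > 0 else _NEGATIVE_SENT
            out = out + " " + extra.format(**_SLOTS[cell.gender])
        # hallucination injection
        rate = config.hallucination_rate.get(cell.gender, 0.0)
        if rate and rng.random() < rate:
            term = _HALLUCINATION_TERMS[int(rng.integers(len(_HALLUCINATION_TERMS)))]
            slots = dict(_SLOTS[cell.gender])
            out = out + f" {slots['S']} has a recent diagnosis of {term}."
        return out

    return SummarizerSpec(name=name, fn=fn, deterministic=True)
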