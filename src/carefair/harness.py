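"""Factorial summary-generation harness.

Every document pair is summarised in both gender versions, by every
summarisation model, at every maximum-token level — so per document there
are 2 x n_models x n_levels cells (48 in the reference design of 4 models
and 6 levels). Real LLM adapters plug in behind :class:`SummarizerSpec`;
the shipped summarisers are deterministic extractive mocks so the whole
pipeline runs at desk scale with no model downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import CounterfactualPair
from .text import split_sentences

__all__ = [
    "NONE_LEVEL",
    "DEFAULT_LEVELS",
    "GENDERS",
    "GenerationGrid",
    "SummaryRecord",
    "SummarizerSpec",
    "build_grid",
    "run_summarization",
    "mock_summarizer",
    "write_summaries",
    "read_summaries",
]

#: sentinel for the uncapped output-length factor level
NONE_LEVEL = "None"
DEFAULT_LEVELS = ("50", "75", "100", "150", "300", NONE_LEVEL)
GENDERS = ("female", "male")


@dataclass(frozen=True)
class GridCell:
    doc_id: str
    gender: str
    model_name: str
    max_tokens_level: str


@dataclass
class GenerationGrid:
    doc_ids: tuple[str, ...]
    model_names: tuple[str, ...]
    max_tokens_levels: tuple[str, ...]

    @property
    def cells(self) -> list[GridCell]:
        return [
            GridCell(d, g, m, l)
            for d in self.doc_ids
            for g in GENDERS
            for m in self.model_names
            for l in self.max_tokens_levels
        ]

    def __len__(self) -> int:
        return len(self.doc_ids) * 2 * len(self.model_names) * len(self.max_tokens_levels)


@dataclass
class SummaryRecord:
    doc_id: str
    gender: str
    model_name: str
    max_tokens_level: str
    summary_text: str
    generation_meta: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.doc_id, self.gender, self.model_name, self.max_tokens_level)


@dataclass
class SummarizerSpec:
    """Pluggable summariser: callable (text, max_tokens_level, cell) -> text.

    Deterministic specs must return identical output on identical input; the
    cell key is passed so mock summarisers can derive per-cell seeds.
    """

    name: str
    fn: Callable[[str, str, GridCell], str]
    deterministic: bool = True

    def summarize(self, text: str, level: str, cell: GridCell) -> str:
        return self.fn(text, level, cell)


def build_grid(
    doc_ids: Sequence[str],
    models: Sequence[str],
    levels: Sequence[str] = DEFAULT_LEVELS,
) -> GenerationGrid:
    """Full cross product: |docs| x 2 genders x |models| x |levels| cells."""
    if not models or not levels:
        raise ValueError("models and levels must be non-empty")
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate doc_ids in grid")
    return GenerationGrid(tuple(str(d) for d in doc_ids), tuple(models), tuple(str(l) for l in levels))


def run_summarization(
    pairs: Sequence[CounterfactualPair],
    spec: SummarizerSpec | Mapping[str, SummarizerSpec],
    grid: GenerationGrid,
) -> list[SummaryRecord]:
    """Produce exactly one SummaryRecord per grid cell; female cells summarise
    the female text, male cells the male text."""
    by_id = {p.doc_id: p for p in pairs}
    missing = [d for d in grid.doc_ids if d not in by_id]
    if missing:
        raise ValueError(f"no pair for grid doc_ids: {missing[:5]}")
    if isinstance(spec, SummarizerSpec):
        specs = {m: spec for m in grid.model_names}
    else:
        specs = dict(spec)
        absent = [m for m in grid.model_names if m not in specs]
        if absent:
            raise ValueError(f"no summariser spec for models: {absent}")
    records = []
    for cell in grid.cells:
        pair = by_id[cell.doc_id]
        text = pair.text_for(cell.gender)
        s = specs[cell.model_name]
        try:
            out = s.summarize(text, cell.max_tokens_level, cell)
        except Exception as exc:  # re-raise with cell context
            raise RuntimeError(f"summariser {s.name!r} failed on cell {cell}") from exc
        if not out.strip():
            raise ValueError(f"summariser {s.name!r} returned empty text for {cell}")
        records.append(
            SummaryRecord(
                cell.doc_id,
                cell.gender,
                cell.model_name,
                cell.max_tokens_level,
                out,
                {"summarizer": s.name, "deterministic": s.deterministic},
            )
        )
    return records


#: default sentence budget per max-tokens level for the extractive mock
DEFAULT_SENTENCES_PER_LEVEL = {
    "50": 1,
    "75": 2,
    "100": 3,
    "150": 4,
    "300": 6,
    NONE_LEVEL: None,  # whole text
}


def mock_summarizer(
    max_sentences_per_level: Mapping[str, int | None] | None = None,
    name: str = "mock",
) -> SummarizerSpec:
    """Extractive mock: returns the first k sentences for the level's k
    (whole text at the uncapped level). Purely deterministic."""
    mapping = dict(max_sentences_per_level or DEFAULT_SENTENCES_PER_LEVEL)

    def fn(text: str, level: str, cell: GridCell) -> str:
        if level not in mapping:
            raise KeyError(f"unknown max-tokens level {level!r}")
        k = mapping[level]
        if k is None:
            return text
        sents = split_sentences(text)
        return " ".join(sents[:k]) if sents else text

    return SummarizerSpec(name=name, fn=fn, deterministic=True)


def write_summaries(records: Iterable[SummaryRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r)) + "\n")


def read_summaries(path: str | Path) -> list[SummaryRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(SummaryRecord(**json.loads(line)))
    return out
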