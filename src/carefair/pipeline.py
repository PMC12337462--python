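"""End-to-end orchestration: prepare -> summarise -> sentiment / themes /
words / hallucination -> report.

Both genders of every pair are processed by byte-identical code paths and
parameters; all randomness flows from a single root seed expanded per stage,
and the manifest records versions, seeds and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .corpus import (
    CounterfactualPair,
    GenderLexicon,
    dedupe_near,
    filter_eligible,
    make_pair,
    read_corpus,
    write_pairs,
)
from .harness import (
    DEFAULT_LEVELS,
    SummarizerSpec,
    build_grid,
    mock_summarizer,
    run_summarization,
    write_summaries,
)
from .hallucination import audit, load_medical_terms, opportunity_count
from .sentiment import (
    SentimentMixedModel,
    cluster_bootstrap,
    estimate_gender_emm,
    get_metric,
    score_summaries,
    screen_metric_bias,
)
from .synthetic import SyntheticConfig, biased_mock_summarizer, generate_pairs
from .themes import load_theme_lexicons, theme_bias_table
from .words import analyze_linguistic_bias, build_doc_term_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "prepare_pairs"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 7
    corpus_path: str | None = None  # CSV/JSONL corpus; None -> synthetic
    synthetic: SyntheticConfig | None = None
    models: Sequence[str] = ("mock_a", "mock_b")
    levels: Sequence[str] = DEFAULT_LEVELS
    metric: str = "lexicon"
    alpha: float = 0.05
    min_words: int = 200
    max_words: int = 500
    bootstrap: int = 0
    exposure_adjusted_words: bool = True
    lexicon_dir: str | None = None
    terms_path: str | None = None
    random_slopes: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for p in (self.corpus_path, self.lexicon_dir, self.terms_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def prepare_pairs(
    corpus_path: str | Path,
    min_words: int = 200,
    max_words: int = 500,
    lexicon: GenderLexicon | None = None,
):
    """Filter, dedupe and gender-swap an input corpus into validated pairs."""
    docs = read_corpus(corpus_path)
    kept, report = filter_eligible(docs, min_words, max_words)
    before = len(kept)
    kept = dedupe_near(kept)
    report.n_near_duplicate = before - len(kept)
    report.n_kept = len(kept)
    lex = lexicon or GenderLexicon.from_tsv()
    pairs = [make_pair(d, lex) for d in kept]
    return pairs, report


def _summarizer_for(name: str, cfg: RunConfig) -> SummarizerSpec:
    if name.startswith("biased"):
        syn = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
        spec = biased_mock_summarizer(syn, name=name)
    else:
        spec = mock_summarizer(name=name)
    return spec


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write Table-style CSVs, the hallucination
    summary, the metric screen and a JSON manifest. Returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "carefair_version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
            logger.info("stage %s done in %.2fs %s", name, time.time() - t0, info)

        return done

    # -- prepare ---------------------------------------------------------
    fin = stage("prepare")
    if config.corpus_path is not None:
        pairs, report = prepare_pairs(config.corpus_path, config.min_words, config.max_words)
        manifest["filter_report"] = report.as_dict()
    else:
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        manifest["synthetic_seed"] = syn.seed
        pairs = generate_pairs(syn)
    validated = [p for p in pairs if p.validated]
    if not validated:
        raise RuntimeError("stage prepare: no validated pairs")
    write_pairs(validated, out / "pairs.jsonl")
    fin(n_pairs=len(pairs), n_validated=len(validated))

    # -- summarise -------------------------------------------------------
    fin = stage("summarize")
    grid = build_grid([p.doc_id for p in validated], list(config.models), list(config.levels))
    specs = {m: _summarizer_for(m, config) for m in config.models}
    records = run_summarization(validated, specs, grid)
    write_summaries(records, out / "summaries.jsonl")
    fin(n_cells=len(grid), n_records=len(records))

    # -- metric screen + sentiment ----------------------------------------
    fin = stage("sentiment")
    metric = get_metric(config.metric)
    screen = screen_metric_bias(validated, metric, config.alpha)
    (out / "metric_screen.json").write_text(json.dumps(asdict(screen), indent=2))
    table = score_summaries(records, metric)
    model_obj = SentimentMixedModel(table, random_slopes=config.random_slopes)
    fit = model_obj.fit()
    coef = fit.fe_params.to_frame("estimate")
    coef["std_error"] = fit.bse
    coef["z"] = fit.zvalues
    coef["p"] = fit.pvalues
    coef.to_csv(out / "sentiment_coefficients.csv")
    emms = estimate_gender_emm(fit)
    import pandas as pd

    pd.DataFrame([asdict(e) for e in emms]).to_csv(out / "sentiment_emm.csv", index=False)
    if config.bootstrap > 0:
        cis = cluster_bootstrap(
            table, config.bootstrap, config.seed + 1, random_slopes=config.random_slopes
        )
        cis.to_csv(out / "sentiment_bootstrap.csv")
    fin(converged=fit.converged, metric_passed=screen.passed)

    # -- themes ------------------------------------------------------------
    fin = stage("themes")
    lexicons = load_theme_lexicons(config.lexicon_dir)
    theme_table = theme_bias_table(records, lexicons)
    theme_table.to_csv(out / "themes.csv", index=False)
    fin(n_tests=len(theme_table))

    # -- words --------------------------------------------------------------
    fin = stage("words")
    dtm = build_doc_term_matrix(records)
    dtm.save(out / "doc_term_matrix")
    word_tables = []
    for m in config.models:
        word_tables.append(
            analyze_linguistic_bias(
                dtm, m, config.alpha, exposure_adjusted=config.exposure_adjusted_words
            )
        )
    words = pd.concat(word_tables, ignore_index=True)
    words.to_csv(out / "words.csv", index=False)
    n_dual = int(words["dual_significant"].sum())
    fin(n_lemmas=len(words), n_dual_significant=n_dual)

    # -- hallucination -------------------------------------------------------
    fin = stage("hallucination")
    terms = load_medical_terms(config.terms_path)
    _, counts = audit(validated, records, terms)
    halluc = {
        "n_terms": len(terms),
        "opportunities": opportunity_count(
            len(validated), 2, len(config.models) * len(config.levels), len(terms)
        ),
        "counts": counts.to_dict(orient="records"),
        "total": int(counts["n_hallucinated"].sum()) if len(counts) else 0,
        "by_gender": counts.groupby("gender")["n_hallucinated"].sum().to_dict()
        if len(counts)
        else {},
    }
    (out / "hallucination.json").write_text(json.dumps(halluc, indent=2))
    fin(total=halluc["total"])

    manifest["n_dual_significant_words"] = n_dual
    manifest["alpha"] = config.alpha
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
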