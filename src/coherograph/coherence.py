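"""Local and global semantic-coherence metrics and participant-level scoring.

Given a section's sentence vectors S = (s_1, ..., s_N):

* **Local (first-order) coherence** is the cosine similarity between
  adjacent sentences, summed over the N-1 pairs. In the default ``pairs``
  mode the sum is divided by N-1 (the mean over pairs, so N identical
  sentences score exactly 1). The ``paper_verbatim`` mode divides the same
  sum by N instead, reproducing a printed variant of the formula in which
  the identity case scores (N-1)/N.

* **Global coherence** is the cosine similarity between each sentence and
  the centroid s_mean = (1/N) sum_i s_i. The default ``terms`` mode
  averages over all N sentences; ``paper_verbatim`` sums only the first
  N-1 terms and divides by N.

Scores are undefined (MISSING, represented as None) when too few usable
sentences exist: local needs N >= 2, global needs N >= 1 and a nonzero
centroid. MISSING is never coerced to 0; participant-level means are
unweighted averages over the sections with defined scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .embeddings import (
    MISSING,
    EmbeddingModel,
    SentenceVectorSequence,
    cosine_similarity,
    embed_sentences,
)
from .preprocess import PreprocessedSection, PreprocessedTranscript

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoherenceConfig:
    """Scoring modes.

    local_denominator: "pairs" (mean over the N-1 adjacent pairs, default)
        or "paper_verbatim" (divide the same sum by N).
    global_denominator: "terms" (mean over all N sentences, default) or
        "paper_verbatim" (sum N-1 terms, divide by N).
    aggregation: "section" scores each emotion's answer as one sequence
        (default); "question" scores each delimited question answer
        separately and averages over question answers.
    """

    local_denominator: str = "pairs"
    global_denominator: str = "terms"
    aggregation: str = "section"

    def __post_init__(self) -> None:
        if self.local_denominator not in ("pairs", "paper_verbatim"):
            raise ValueError(f"unknown local denominator mode: {self.local_denominator!r}")
        if self.global_denominator not in ("terms", "paper_verbatim"):
            raise ValueError(f"unknown global denominator mode: {self.global_denominator!r}")
        if self.aggregation not in ("section", "question"):
            raise ValueError(f"unknown aggregation mode: {self.aggregation!r}")


@dataclass
class SectionScores:
    emotion: str
    model_name: str
    local: float | None
    global_: float | None
    n_sentences_used: int


@dataclass
class ParticipantScores:
    participant_id: str
    model_name: str
    local_mean: float | None
    global_mean: float | None
    sections_contributing: int
    section_scores: list[SectionScores] = field(default_factory=list)


def local_coherence(seq: SentenceVectorSequence, denominator: str = "pairs") -> float | None:
    """Adjacent-sentence cosine similarity; MISSING when N < 2."""
    n = seq.n
    if n < 2:
        return MISSING
    total = math.fsum(
        cosine_similarity(seq.vectors[i], seq.vectors[i + 1]) for i in range(n - 1)
    )
    if denominator == "pairs":
        return total / (n - 1)
    if denominator == "paper_verbatim":
        return total / n
    raise ValueError(f"unknown denominator mode: {denominator!r}")


def global_coherence(seq: SentenceVectorSequence, denominator: str = "terms") -> float | None:
    """Cosine similarity of each sentence to the centroid of all sentences;
    MISSING when N = 0 or the centroid has zero norm."""
    n = seq.n
    if n == 0:
        return MISSING
    # exact (order-independent) centroid: permutation invariance holds
    # bit-for-bit, not just to rounding
    dim = seq.vectors[0].shape[0]
    s_mean = np.array(
        [math.fsum(v[j] for v in seq.vectors) / n for j in range(dim)]
    )
    if float(np.linalg.norm(s_mean)) == 0.0:
        return MISSING
    if denominator == "terms":
        return math.fsum(cosine_similarity(v, s_mean) for v in seq.vectors) / n
    if denominator == "paper_verbatim":
        if n == 1:
            return MISSING
        return math.fsum(cosine_similarity(seq.vectors[i], s_mean) for i in range(n - 1)) / n
    raise ValueError(f"unknown denominator mode: {denominator!r}")


def score_section(
    section: PreprocessedSection,
    model: EmbeddingModel,
    config: CoherenceConfig = CoherenceConfig(),
) -> SectionScores:
    """Score one emotion section under one embedding model.

    In "question" aggregation, each delimited answer part is scored
    separately and the part scores are averaged (parts with undefined
    scores are excluded); in "section" aggregation all of the section's
    sentences form one sequence.
    """
    if config.aggregation == "question" and section.part_slices:
        parts = [
            section.sentences[lo:hi] for lo, hi in section.part_slices if hi > lo
        ]
    else:
        parts = [section.sentences]
    locals_: list[float] = []
    globals_: list[float] = []
    n_used = 0
    for sentences in parts:
        seq = embed_sentences(sentences, model)
        n_used += seq.n
        lc = local_coherence(seq, config.local_denominator)
        gc = global_coherence(seq, config.global_denominator)
        if lc is not MISSING:
            locals_.append(lc)
        if gc is not MISSING:
            globals_.append(gc)
    return SectionScores(
        emotion=section.emotion,
        model_name=model.name,
        local=float(np.mean(locals_)) if locals_ else MISSING,
        global_=float(np.mean(globals_)) if globals_ else MISSING,
        n_sentences_used=n_used,
    )


def score_participant(
    pt: PreprocessedTranscript,
    models: list[EmbeddingModel],
    config: CoherenceConfig = CoherenceConfig(),
) -> list[ParticipantScores]:
    """Score a preprocessed transcript under each model.

    Per model: a SectionScores for each emotion section, then the
    unweighted mean over sections with defined scores. With two models
    this yields the four-metric design (local/global x two models).
    """
    out = []
    for model in models:
        section_scores = [score_section(sec, model, config) for sec in pt.sections]
        locals_ = [s.local for s in section_scores if s.local is not MISSING]
        globals_ = [s.global_ for s in section_scores if s.global_ is not MISSING]
        contributing = sum(
            1
            for s in section_scores
            if s.local is not MISSING or s.global_ is not MISSING
        )
        if contributing == 0:
            logger.warning(
                "participant %s: no section produced a defined score under model %s",
                pt.participant_id,
                model.name,
            )
        out.append(
            ParticipantScores(
                participant_id=pt.participant_id,
                model_name=model.name,
                local_mean=float(np.mean(locals_)) if locals_ else MISSING,
                global_mean=float(np.mean(globals_)) if globals_ else MISSING,
                sections_contributing=contributing,
                section_scores=section_scores,
            )
        )
    return out


def score_cohort(
    transcripts: list[PreprocessedTranscript],
    models: list[EmbeddingModel],
    config: CoherenceConfig = CoherenceConfig(),
):
    """Score many participants -> tidy pandas DataFrame.

    Columns: participant_id, then local_<model> / global_<model> per
    model, plus provenance (word counts, sentences used/skipped).
    """
    import pandas as pd

    rows = []
    for pt in transcripts:
        row: dict = {
            "participant_id": pt.participant_id,
            "word_count": pt.word_count,
            "unique_word_count": pt.unique_word_count,
        }
        for ps in score_participant(pt, models, config):
            row[f"local_{ps.model_name}"] = (
                np.nan if ps.local_mean is MISSING else ps.local_mean
            )
            row[f"global_{ps.model_name}"] = (
                np.nan if ps.global_mean is MISSING else ps.global_mean
            )
            row[f"sections_contributing_{ps.model_name}"] = ps.sections_contributing
            row[f"sentences_used_{ps.model_name}"] = sum(
                s.n_sentences_used for s in ps.section_scores
            )
        rows.append(row)
    return pd.DataFrame(rows)
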