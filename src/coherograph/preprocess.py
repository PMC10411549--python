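"""Preprocessing chain: filler removal, stopword removal, lemmatization.

Chain order is fixed (fillers -> stopwords -> lemmatize); lemmatizing
before stopword removal could change lexicon membership, so the order is
not configurable. Lexicon matching lowercases both sides; emitted tokens
keep their original (or lemma) casing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _ilr
from pathlib import Path
from typing import Callable

from .transcripts import Transcript

logger = logging.getLogger(__name__)

Lemmatizer = Callable[[str], str]


def _load_lexicon_file(path: Path) -> frozenset[str]:
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def _resource_path(name: str) -> Path:
    return Path(str(_ilr.files("coherograph").joinpath("resources", name)))


@dataclass(frozen=True)
class Lexicons:
    """Filler / stopword / conjunction inventories (case-normalized to lower)."""

    fillers: frozenset[str]
    stopwords: frozenset[str]
    conjunction_splitters: tuple[str, ...] = ()

    @classmethod
    def from_files(
        cls,
        filler_file: str | Path | None = None,
        stopword_file: str | Path | None = None,
        conjunction_file: str | Path | None = None,
    ) -> "Lexicons":
        filler_file = Path(filler_file) if filler_file else _resource_path("fillers_de.txt")
        stopword_file = Path(stopword_file) if stopword_file else _resource_path("stopwords_de.txt")
        conjunction_file = (
            Path(conjunction_file) if conjunction_file else _resource_path("conjunctions_de.txt")
        )
        return cls(
            fillers=_load_lexicon_file(filler_file),
            stopwords=_load_lexicon_file(stopword_file),
            conjunction_splitters=tuple(sorted(_load_lexicon_file(conjunction_file))),
        )

    @classmethod
    def default(cls) -> "Lexicons":
        """Shipped German lists. Analyses are sensitive to the inventory used;
        pass explicit files to reproduce a specific study's preprocessing."""
        return cls.from_files()


def identity_lemmatizer(token: str) -> str:
    return token


class TableLemmatizer:
    """Table-driven lemmatizer: surface form -> lemma, unknown forms pass through.

    Lookup is case-insensitive; table files are TSV (surface<TAB>lemma),
    '#' comments allowed.
    """

    def __init__(self, table: dict[str, str]):
        self.table = {k.lower(): v for k, v in table.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "TableLemmatizer":
        table = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'surface<TAB>lemma'")
            table[parts[0]] = parts[1]
        return cls(table)

    def __call__(self, token: str) -> str:
        return self.table.get(token.lower(), token)


@dataclass
class PreprocessedSection:
    emotion: str
    sentences: list[list[str]]  # retained sentences, post-filter post-lemma
    dropped_sentence_count: int = 0
    removed_token_count: int = 0
    # answer-part boundaries as sentence index ranges, for per-question scoring
    part_slices: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class PreprocessedTranscript:
    participant_id: str
    sections: list[PreprocessedSection]
    word_count: int  # raw tokens across annotated answer sentences
    unique_word_count: int  # distinct raw tokens (case-insensitive)
    processed_word_count: int  # tokens surviving the chain


def remove_fillers(tokens: list[str], lexicons: Lexicons) -> list[str]:
    """Drop verbal fillers ("ehm", ...); order preserved, may return []."""
    return [t for t in tokens if t.lower() not in lexicons.fillers]


def remove_stopwords(tokens: list[str], lexicons: Lexicons) -> list[str]:
    return [t for t in tokens if t.lower() not in lexicons.stopwords]


def lemmatize(tokens: list[str], lemmatizer: Lemmatizer) -> list[str]:
    """Map each token to its dictionary form; a failing lemmatizer call keeps
    the surface form (logged)."""
    out = []
    for t in tokens:
        try:
            out.append(lemmatizer(t))
        except Exception:  # lemmatizer contract violation; degrade gracefully
            logger.warning("lemmatizer failed on token %r; keeping surface form", t)
            out.append(t)
    return out


def preprocess_section(
    emotion: str,
    sentences: list[list[str]],
    lexicons: Lexicons,
    lemmatizer: Lemmatizer = identity_lemmatizer,
    part_slices: list[tuple[int, int]] | None = None,
) -> PreprocessedSection:
    kept: list[list[str]] = []
    kept_index: list[int] = []  # original sentence index of each kept sentence
    dropped = 0
    removed = 0
    for i, tokens in enumerate(sentences):
        filtered = remove_stopwords(remove_fillers(tokens, lexicons), lexicons)
        removed += len(tokens) - len(filtered)
        if filtered:
            kept.append(lemmatize(filtered, lemmatizer))
            kept_index.append(i)
        else:
            dropped += 1
    # remap answer-part ranges onto kept-sentence indices
    new_slices: list[tuple[int, int]] = []
    if part_slices:
        for start, stop in part_slices:
            lo = sum(1 for j in kept_index if j < start)
            hi = sum(1 for j in kept_index if j < stop)
            new_slices.append((lo, hi))
    return PreprocessedSection(
        emotion=emotion,
        sentences=kept,
        dropped_sentence_count=dropped,
        removed_token_count=removed,
        part_slices=new_slices,
    )


def preprocess_transcript(
    t: Transcript,
    lexicons: Lexicons,
    lemmatizer: Lemmatizer = identity_lemmatizer,
) -> PreprocessedTranscript:
    """Run the full chain over an annotated transcript.

    Question texts are never part of the analysis (only answer sentences
    are annotated). Sections whose every sentence is removed are retained
    with an empty sentence list and a warning.
    """
    sections = []
    raw_tokens: list[str] = []
    processed = 0
    for sec in t.sections:
        if sec.sentences is None:
            raise ValueError(
                f"section {sec.emotion!r} of {t.participant_id!r} is not annotated; "
                "call annotate_sentences first"
            )
        sent_tokens = [s.tokens for s in sec.sentences]
        for toks in sent_tokens:
            raw_tokens.extend(toks)
        ps = preprocess_section(
            sec.emotion, sent_tokens, lexicons, lemmatizer, sec.part_slices
        )
        if not ps.sentences:
            logger.warning(
                "participant %s, section %s: no sentences survived preprocessing",
                t.participant_id,
                sec.emotion,
            )
        processed += sum(len(s) for s in ps.sentences)
        sections.append(ps)
    return PreprocessedTranscript(
        participant_id=t.participant_id,
        sections=sections,
        word_count=len(raw_tokens),
        unique_word_count=len({w.lower() for w in raw_tokens}),
        processed_word_count=processed,
    )
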