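"""Reading, writing and sentence annotation of structured interview transcripts.

A transcript holds one participant's semi-structured emotion interview:
four sections (sadness, fear, anger, happiness), each with its question
prompts and the participant's answer text. Coherence metrics are computed
over sentences, so sentence boundaries matter; the reference path is
*marker* mode, where boundaries were placed by a human annotator as
sentence-final punctuation (a sentence contains at least a subject and a
verb, main clauses keep their subordinate clauses, coordinated main
clauses are separated). *Automatic* mode is a punctuation-based
convenience splitter and only an approximation of that guideline.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path

EMOTIONS = ("sadness", "fear", "anger", "happiness")

# Coordinating conjunctions that separate main clauses. Used by the
# automatic splitter to break "..., und ..." style coordinations; marker
# mode relies on annotator-placed punctuation alone.
DEFAULT_CONJUNCTIONS = ("und", "aber", "oder", "denn", "sondern", "and", "but", "or")

_SENT_FINAL = ".!?…"
# edge punctuation stripped from tokens; word-internal hyphens survive
_STRIP_CHARS = ".,;:!?…\"'„“”‘’«»()[]{}–—-/\\*"


class TranscriptParseError(ValueError):
    """Malformed transcript file; message names the offending line or field."""


class TranscriptValidationError(ValueError):
    """Structurally valid file with invalid content (e.g. unknown emotion)."""


@dataclass
class Sentence:
    tokens: list[str]
    boundary_source: str  # "manual_marker" | "automatic_split"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("Sentence requires at least one token")


@dataclass
class EmotionSection:
    emotion: str
    question_texts: list[str] = field(default_factory=list)
    answer_texts: list[str] = field(default_factory=list)  # one per question
    sentences: list[Sentence] | None = None  # populated by annotate_sentences
    # sentence index ranges per answer part, parallel to answer_texts
    part_slices: list[tuple[int, int]] | None = None

    @property
    def answer_text(self) -> str:
        return "\n".join(self.answer_texts)

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise TranscriptValidationError(f"unknown emotion label: {self.emotion!r}")


@dataclass
class Transcript:
    participant_id: str
    sections: list[EmotionSection]
    language_tag: str = "de"
    missing_emotions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise TranscriptValidationError("participant_id must be non-empty")
        seen: set[str] = set()
        for s in self.sections:
            if s.emotion in seen:
                raise TranscriptValidationError(f"duplicate emotion section: {s.emotion}")
            seen.add(s.emotion)

    def section(self, emotion: str) -> EmotionSection | None:
        for s in self.sections:
            if s.emotion == emotion:
                return s
        return None


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with edge-punctuation stripping.

    Text is NFC-normalized first; case is preserved (German nouns are
    case-bearing and embedding models may be case-sensitive).
    """
    out = []
    for raw in unicodedata.normalize("NFC", text).split():
        tok = raw.strip(_STRIP_CHARS)
        if tok:
            out.append(tok)
    return out


def _split_on_punctuation(text: str) -> list[str]:
    return [c for c in re.split(rf"(?<=[{_SENT_FINAL}])\s+", text) if c.strip()]


def annotate_sentences(
    section: EmotionSection,
    mode: str = "marker",
    conjunctions: tuple[str, ...] = DEFAULT_CONJUNCTIONS,
) -> EmotionSection:
    """Populate ``section.sentences`` from its answer texts.

    marker mode: splits exactly at annotator-inserted sentence-final
    punctuation. automatic mode: the same punctuation split, plus a split
    at commas directly followed by a listed coordinating conjunction
    (coordinated main clauses are separate sentences; subordinate-clause
    commas never split). No sentence spans an answer-part boundary.
    A section with empty answer text yields zero sentences (no error).
    Pure function of (answer text, mode, conjunction list).
    """
    if mode not in ("marker", "automatic"):
        raise ValueError(f"unknown annotation mode: {mode!r}")
    source = "manual_marker" if mode == "marker" else "automatic_split"
    conj_re = None
    if mode == "automatic" and conjunctions:
        alt = "|".join(re.escape(c) for c in conjunctions)
        conj_re = re.compile(rf",\s+(?=(?:{alt})\b)", re.IGNORECASE)

    sentences: list[Sentence] = []
    part_slices: list[tuple[int, int]] = []
    for part in section.answer_texts:
        start = len(sentences)
        chunks = _split_on_punctuation(part)
        if conj_re is not None:
            chunks = [sub for c in chunks for sub in conj_re.split(c)]
        for chunk in chunks:
            tokens = tokenize(chunk)
            if tokens:
                sentences.append(Sentence(tokens=tokens, boundary_source=source))
        part_slices.append((start, len(sentences)))
    return replace(section, sentences=sentences, part_slices=part_slices)


def annotate_transcript(
    t: Transcript,
    mode: str = "marker",
    conjunctions: tuple[str, ...] = DEFAULT_CONJUNCTIONS,
) -> Transcript:
    return replace(
        t, sections=[annotate_sentences(s, mode, conjunctions) for s in t.sections]
    )


# ---------------------------------------------------------------------------
# Structured (JSON) format: one participant per file.

def _read_structured(path: Path) -> Transcript:
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise TranscriptParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    for key in ("participant_id", "sections"):
        if key not in data:
            raise TranscriptParseError(f"{path}: missing required field {key!r}")
    sections = []
    present = set()
    for i, rec in enumerate(data["sections"]):
        if "emotion" not in rec:
            raise TranscriptParseError(f"{path}: section {i} missing 'emotion' field")
        emotion = rec["emotion"]
        if emotion not in EMOTIONS:
            raise TranscriptValidationError(f"{path}: unknown emotion label {emotion!r}")
        answers = rec.get("answers")
        if answers is None:
            answers = [rec.get("answer", "")]
        sections.append(
            EmotionSection(
                emotion=emotion,
                question_texts=list(rec.get("questions", [])),
                answer_texts=[str(a) for a in answers],
            )
        )
        present.add(emotion)
    sections.sort(key=lambda s: EMOTIONS.index(s.emotion))
    return Transcript(
        participant_id=str(data["participant_id"]),
        sections=sections,
        language_tag=str(data.get("language", "de")),
        missing_emotions=tuple(e for e in EMOTIONS if e not in present),
    )


def _write_structured(t: Transcript, path: Path) -> None:
    data = {
        "participant_id": t.participant_id,
        "language": t.language_tag,
        "sections": [
            {
                "emotion": s.emotion,
                "questions": s.question_texts,
                "answers": s.answer_texts,
            }
            for s in t.sections
        ],
    }
    path.write_text(json.dumps(data, ensure_ascii=False, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Plain format: "## <emotion>" section headers, "? " question lines, answer
# lines in between. Escaping rule: any answer line beginning with "## ",
# "? ", "# " or a backslash is written with a leading backslash; the reader
# strips one leading backslash from such lines.

_ESCAPABLE = ("## ", "? ", "# ", "\\")


def _escape_line(line: str) -> str:
    return "\\" + line if line.startswith(_ESCAPABLE) else line


def _unescape_line(line: str) -> str:
    if line.startswith("\\") and line[1:].startswith(_ESCAPABLE):
        return line[1:]
    return line


def _read_plain(path: Path) -> Transcript:
    participant_id = ""
    language = "de"
    sections: list[EmotionSection] = []
    current: EmotionSection | None = None
    answer_lines: list[str] = []

    def flush_answer() -> None:
        if current is not None and current.question_texts and answer_lines:
            current.answer_texts.append("\n".join(answer_lines).strip())
            answer_lines.clear()

    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if line.startswith("# participant:"):
            participant_id = line.split(":", 1)[1].strip()
        elif line.startswith("# language:"):
            language = line.split(":", 1)[1].strip()
        elif line.startswith("## "):
            flush_answer()
            emotion = line[3:].strip().lower()
            if emotion not in EMOTIONS:
                raise TranscriptValidationError(
                    f"{path}:{lineno}: unknown emotion label {emotion!r}"
                )
            current = EmotionSection(emotion=emotion)
            sections.append(current)
        elif line.startswith("? "):
            if current is None:
                raise TranscriptParseError(
                    f"{path}:{lineno}: question line before any section header"
                )
            flush_answer()
            current.question_texts.append(line[2:])
        else:
            if current is None:
                if line.strip():
                    raise TranscriptParseError(
                        f"{path}:{lineno}: answer text before any section header"
                    )
                continue
            if line.strip():
                answer_lines.append(_unescape_line(line))
            elif answer_lines:
                answer_lines.append("")
    flush_answer()
    if not participant_id:
        raise TranscriptParseError(f"{path}: missing '# participant:' header")
    # a question with no answer lines still needs an (empty) answer slot
    for s in sections:
        while len(s.answer_texts) < len(s.question_texts):
            s.answer_texts.append("")
    present = {s.emotion for s in sections}
    sections.sort(key=lambda s: EMOTIONS.index(s.emotion))
    return Transcript(
        participant_id=participant_id,
        sections=sections,
        language_tag=language,
        missing_emotions=tuple(e for e in EMOTIONS if e not in present),
    )


def _write_plain(t: Transcript, path: Path) -> None:
    lines = [f"# participant: {t.participant_id}", f"# language: {t.language_tag}", ""]
    for s in t.sections:
        lines.append(f"## {s.emotion}")
        answers = list(s.answer_texts)
        while len(answers) < len(s.question_texts):
            answers.append("")
        for q, a in zip(s.question_texts, answers):
            lines.append(f"? {q}")
            for al in a.split("\n"):
                lines.append(_escape_line(al))
            lines.append("")
    path.write_text("\n".join(lines).rstrip("\n") + "\n", encoding="utf-8")


def read_transcript(path: str | Path, format: str = "structured") -> Transcript:
    """Read one participant's transcript.

    ``format`` is "structured" (JSON record) or "plain_with_markers"
    (header-marked UTF-8 text). Raw answer text is preserved verbatim.
    Sections absent from the file are recorded in
    ``Transcript.missing_emotions``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "structured":
        return _read_structured(path)
    if format in ("plain", "plain_with_markers"):
        return _read_plain(path)
    raise ValueError(f"unknown transcript format: {format!r}")


def write_transcript(t: Transcript, path: str | Path, format: str = "structured") -> None:
    path = Path(path)
    if format == "structured":
        _write_structured(t, path)
    elif format in ("plain", "plain_with_markers"):
        _write_plain(t, path)
    else:
        raise ValueError(f"unknown transcript format: {format!r}")


def read_transcript_dir(directory: str | Path, format: str = "structured") -> list[Transcript]:
    """Read every transcript file in a directory, sorted by filename."""
    directory = Path(directory)
    suffix = ".json" if format == "structured" else ".txt"
    return [
        read_transcript(p, format) for p in sorted(directory.glob(f"*{suffix}"))
    ]
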