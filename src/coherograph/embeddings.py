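"""Word-embedding models: text-format loaders, OOV policy, sentence vectors.

Two text dialects are supported: word2vec-text (a "<vocab> <dim>" header
line, then one "word v1 ... vd" line per word) and GloVe-text (the same
rows, no header). Binary word2vec files are not supported. A sentence
vector is the arithmetic mean of the embedding vectors of the sentence's
in-vocabulary tokens; out-of-vocabulary tokens are left out, and a
sentence with no in-vocabulary token is MISSING (represented as None) and
excluded downstream — it never enters a cosine as a zero vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel for an unobtainable value (all-OOV sentence, empty section, ...)
MISSING = None


class EmbeddingFormatError(ValueError):
    """Malformed vector file; message names the offending line."""


@dataclass
class EmbeddingModel:
    """Vocabulary-to-vector map of fixed dimension.

    OOV policy for case-sensitive models: exact match first, then (if
    ``lowercase_fallback``) the lowercased form; both misses -> OOV.
    """

    name: str
    dimension: int
    vectors: dict[str, np.ndarray]
    case_sensitive: bool = True
    lowercase_fallback: bool = True

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("embedding model has empty vocabulary")
        if self.dimension <= 0:
            raise ValueError("embedding dimension must be positive")
        for w, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {w!r} has shape {v.shape}, expected ({self.dimension},)"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {w!r} contains NaN/Inf")

    def __contains__(self, token: str) -> bool:
        return self.lookup(token) is not MISSING

    def lookup(self, token: str) -> np.ndarray | None:
        if not self.case_sensitive:
            token = token.lower()
            hit = self.vectors.get(token)
            if hit is None:
                # vocabulary may be cased even if lookup is not
                for cand, vec in self.vectors.items():
                    if cand.lower() == token:
                        return vec
            return hit
        hit = self.vectors.get(token)
        if hit is None and self.lowercase_fallback:
            hit = self.vectors.get(token.lower())
        return hit


@dataclass
class SentenceVectorSequence:
    """Ordered sentence vectors s_1 ... s_N for one section (MISSING removed)."""

    vectors: list[np.ndarray] = field(default_factory=list)
    skipped: int = 0  # sentences dropped for having no in-vocabulary token

    @property
    def n(self) -> int:
        return len(self.vectors)


def _parse_vector_line(line: str, lineno: int, path: Path) -> tuple[str, np.ndarray]:
    parts = line.rstrip("\n").split(" ")
    if len(parts) < 2:
        raise EmbeddingFormatError(f"{path}:{lineno}: expected 'word v1 ... vd'")
    word = parts[0]
    try:
        vec = np.asarray([float(x) for x in parts[1:] if x != ""], dtype=np.float64)
    except ValueError as e:
        raise EmbeddingFormatError(f"{path}:{lineno}: non-numeric vector component") from e
    return word, vec


def load_embeddings(
    path: str | Path,
    dialect: str = "auto",
    name: str | None = None,
    case_sensitive: bool = True,
) -> EmbeddingModel:
    """Load a vector file in word2vec-text or GloVe-text dialect.

    ``auto`` detects the dialect by whether line 1 is exactly two
    integers. Duplicate words: first occurrence wins (logged). Ragged
    vector lengths raise :class:`EmbeddingFormatError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise EmbeddingFormatError(f"{path}: empty vector file")

    start = 0
    declared: tuple[int, int] | None = None
    first = lines[0].split()
    if dialect == "auto":
        if len(first) == 2 and all(p.lstrip("-").isdigit() for p in first):
            dialect = "word2vec_text"
        else:
            dialect = "glove_text"
    if dialect == "word2vec_text":
        if len(first) != 2 or not all(p.isdigit() for p in first):
            raise EmbeddingFormatError(
                f"{path}:1: word2vec_text requires a '<vocab> <dim>' header line"
            )
        declared = (int(first[0]), int(first[1]))
        start = 1
    elif dialect != "glove_text":
        raise ValueError(f"unknown embedding dialect: {dialect!r}")

    vectors: dict[str, np.ndarray] = {}
    dim: int | None = declared[1] if declared else None
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        word, vec = _parse_vector_line(line, lineno, path)
        if dim is None:
            dim = len(vec)
        if len(vec) != dim:
            raise EmbeddingFormatError(
                f"{path}:{lineno}: vector has {len(vec)} components, expected {dim}"
            )
        if word in vectors:
            logger.warning("%s:%d: duplicate word %r ignored (first wins)", path, lineno, word)
            continue
        vectors[word] = vec
    if declared and declared[0] != len(vectors):
        logger.warning(
            "%s: header declares %d words, found %d", path, declared[0], len(vectors)
        )
    return EmbeddingModel(
        name=name or path.stem,
        dimension=int(dim),  # type: ignore[arg-type]
        vectors=vectors,
        case_sensitive=case_sensitive,
    )


def write_embeddings(model: EmbeddingModel, path: str | Path, dialect: str = "word2vec_text") -> None:
    path = Path(path)
    out = []
    if dialect == "word2vec_text":
        out.append(f"{len(model.vectors)} {model.dimension}")
    elif dialect != "glove_text":
        raise ValueError(f"unknown embedding dialect: {dialect!r}")
    for word, vec in model.vectors.items():
        out.append(word + " " + " ".join(repr(float(x)) for x in vec))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def sentence_vector(tokens: list[str], model: EmbeddingModel) -> np.ndarray | None:
    """Mean of in-vocabulary token vectors; MISSING if none are in vocabulary."""
    hits = [v for v in (model.lookup(t) for t in tokens) if v is not MISSING]
    if not hits:
        return MISSING
    return np.mean(np.stack(hits), axis=0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) = u.v / (|u||v|); requires equal dimension and nonzero norms."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def embed_sentences(sentences: list[list[str]], model: EmbeddingModel) -> SentenceVectorSequence:
    """Embed retained sentences; all-OOV and zero-norm sentences are counted
    as skipped and excluded (a zero vector cannot enter a cosine)."""
    seq = SentenceVectorSequence()
    for tokens in sentences:
        vec = sentence_vector(tokens, model)
        if vec is MISSING or float(np.linalg.norm(vec)) == 0.0:
            seq.skipped += 1
        else:
            seq.vectors.append(vec)
    return seq


def embed_sections(
    sections: list, model: EmbeddingModel
) -> list[tuple[str, SentenceVectorSequence]]:
    """Embed each PreprocessedSection -> (emotion, SentenceVectorSequence)."""
    return [(sec.emotion, embed_sentences(sec.sentences, model)) for sec in sections]
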