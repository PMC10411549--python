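import numpy as np
import pytest

from coherograph import EmbeddingModel, EmotionSection, Lexicons, Transcript


@pytest.fixture
def toy_lexicons():
    """Explicit toy lexicons; tests never rely on the shipped inventories."""
    return Lexicons(
        fillers=frozenset({"ehm", "äh"}),
        stopwords=frozenset({"der", "die", "das", "und", "ist", "the", "a"}),
        conjunction_splitters=("und", "aber", "and"),
    )


@pytest.fixture
def toy_model():
    """Hand-built 2-dimensional embedding: a=(1,0), b=(0,1), c=(1,1)."""
    return EmbeddingModel(
        name="toy2d",
        dimension=2,
        vectors={
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
        },
    )


def build_transcript(answers_by_emotion: dict[str, list[str]], pid: str = "P01") -> Transcript:
    """Transcript with one answer part per emotion from plain strings."""
    sections = [
        EmotionSection(emotion=emo, question_texts=["q"], answer_texts=list(parts))
        for emo, parts in answers_by_emotion.items()
    ]
    return Transcript(participant_id=pid, sections=sections)
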