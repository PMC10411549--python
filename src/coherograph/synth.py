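"""Synthetic study material: toy embedding spaces, topic-drift transcripts,
and simulated clinical cohorts.

The generators emulate the *statistical* structure the pipeline consumes,
not natural language. A :class:`TopicSpace` places topic centers on the
unit sphere and scatters a vocabulary around each center, so that
semantically "related" (same-topic) words have nearby vectors. A
topic-drift transcript emits sentences whose word choice follows a latent
topic that switches with probability ``p_switch`` per sentence — the
ground-truth dial for (in)coherence: higher switch rates produce lower
adjacent-sentence similarity. A simulated cohort draws each participant's
switch rate from a Beta distribution and links clinical outcomes to the
standardized latent coherence with stated target correlations, which the
full pipeline should then recover.

Random-number discipline: one root seed fans out to named per-component
streams (stream id = CRC32 of the stream name), so adding a generator
never perturbs the draws of another. Every generator is a pure function
of (spec, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import EmbeddingModel
from .preprocess import Lexicons
from .transcripts import EMOTIONS, EmotionSection, Transcript

QUESTION_TEMPLATES = (
    "Was bedeutet {emotion} für Sie?",
    "Beschreiben Sie eine Situation, in der Sie {emotion} gefühlt haben.",
    "Warum, denken Sie, haben Sie {emotion} in dieser Situation gefühlt?",
)


def _stream(root_seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _default_function_words() -> tuple[tuple[str, ...], tuple[str, ...]]:
    lex = Lexicons.default()
    stop = tuple(sorted(lex.stopwords))[:40]
    fillers = tuple(sorted(lex.fillers))
    return stop, fillers


@dataclass(frozen=True)
class TopicSpace:
    """Geometry of a toy embedding space with topic structure.

    dispersion is a concentration parameter: word vectors are the topic
    center plus isotropic Gaussian noise whose expected squared norm is
    1/dispersion (per-component sd 1/sqrt(dispersion * dim)), then
    renormalized — a simple, dimension-agnostic stand-in for a trained
    model, not a language model. Higher dispersion packs a topic's words
    more tightly around its center. Function words (stopwords, fillers) get
    their own vectors, scattered with no topic structure.
    """

    n_topics: int = 4
    dim: int = 50
    vocab_per_topic: int = 50
    dispersion: float = 8.0
    cosine_ceiling: float = 0.4
    stopword_tokens: tuple[str, ...] = ()
    filler_tokens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.dim < 2:
            raise ValueError("need n_topics >= 1 and dim >= 2")
        if not self.stopword_tokens:
            stop, fill = _default_function_words()
            object.__setattr__(self, "stopword_tokens", stop)
            if not self.filler_tokens:
                object.__setattr__(self, "filler_tokens", fill)

    def topic_word(self, topic: int, j: int) -> str:
        return f"t{topic}w{j}"


@dataclass(frozen=True)
class DriftProfile:
    """Per-sentence topic dynamics and surface statistics of a transcript.

    Defaults are sized so a raw transcript (4 emotion sections x 3
    question answers) averages roughly 240 words with roughly 140-160
    unique words — the scale of real semi-structured emotion interviews.
    """

    p_switch: float = 0.15
    within_topic_noise: float = 1.0  # reserved dial for word-choice scatter
    sentences_per_question: tuple[int, int] = (2, 3)
    words_per_sentence: tuple[int, int] = (5, 11)
    stopword_rate: float = 0.30
    filler_rate: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch must be in [0, 1]")
        if self.stopword_rate + self.filler_rate > 1.0:
            raise ValueError("stopword_rate + filler_rate must be <= 1")
        for lo, hi in (self.sentences_per_question, self.words_per_sentence):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be positive and ordered")


def _topic_centers(space: TopicSpace, rng: np.random.Generator) -> np.ndarray:
    if space.n_topics <= space.dim:
        # random orthonormal directions: pairwise cosine exactly 0
        q, _ = np.linalg.qr(rng.standard_normal((space.dim, space.n_topics)))
        return q.T
    centers = []
    for _ in range(space.n_topics):
        for _attempt in range(2000):
            c = rng.standard_normal(space.dim)
            c /= np.linalg.norm(c)
            if all(abs(float(c @ other)) <= space.cosine_ceiling for other in centers):
                centers.append(c)
                break
        else:
            raise ValueError(
                f"cannot place {space.n_topics} centers with pairwise |cos| <= "
                f"{space.cosine_ceiling} in dimension {space.dim}"
            )
    return np.asarray(centers)


def make_embedding_model(
    space: TopicSpace, seed: int, name: str = "toy"
) -> tuple[EmbeddingModel, dict]:
    """Build a toy embedding model; returns (model, generation log).

    The log reports mean within-topic and between-topic pairwise cosine
    similarity and their margin, so the topic structure is auditable.
    """
    rng = _stream(seed, f"embedding:{name}")
    centers = _topic_centers(space, rng)
    sd = 1.0 / np.sqrt(space.dispersion * space.dim)
    vectors: dict[str, np.ndarray] = {}
    by_topic: list[list[np.ndarray]] = []
    for k in range(space.n_topics):
        topic_vecs = []
        for j in range(space.vocab_per_topic):
            v = centers[k] + sd * rng.standard_normal(space.dim)
            v /= np.linalg.norm(v)
            vectors[space.topic_word(k, j)] = v
            topic_vecs.append(v)
        by_topic.append(topic_vecs)
    for tok in space.stopword_tokens + space.filler_tokens:
        v = rng.standard_normal(space.dim)
        vectors[tok] = v / np.linalg.norm(v)

    within = []
    for vecs in by_topic:
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                within.append(float(vecs[i] @ vecs[j]))
    between = []
    for a in range(space.n_topics):
        for b in range(a + 1, space.n_topics):
            for va in by_topic[a][:10]:  # subsample: the margin, not a census
                for vb in by_topic[b][:10]:
                    between.append(float(va @ vb))
    log = {
        "within_topic_mean_cosine": float(np.mean(within)) if within else 1.0,
        "between_topic_mean_cosine": float(np.mean(between)) if between else 0.0,
    }
    log["margin"] = log["within_topic_mean_cosine"] - log["between_topic_mean_cosine"]
    model = EmbeddingModel(
        name=name, dimension=space.dim, vectors=vectors, case_sensitive=True
    )
    return model, log


def generate_transcript(
    space: TopicSpace,
    profile: DriftProfile,
    seed: int,
    participant_id: str = "SYN",
) -> tuple[Transcript, dict[str, list[int]]]:
    """Generate one four-section topic-drift transcript.

    Sentence boundaries are encoded as sentence-final periods (marker
    mode). Returns the transcript and the ground-truth topic label of
    every sentence, keyed by emotion.
    """
    rng = _stream(seed, f"transcript:{participant_id}")
    sections = []
    topic_labels: dict[str, list[int]] = {}
    for emotion in EMOTIONS:
        topic = int(rng.integers(space.n_topics))
        labels: list[int] = []
        answers = []
        questions = [q.format(emotion=emotion) for q in QUESTION_TEMPLATES]
        for _q in questions:
            lo, hi = profile.sentences_per_question
            n_sent = int(rng.integers(lo, hi + 1))
            sentence_texts = []
            for _s in range(n_sent):
                if space.n_topics > 1 and rng.random() < profile.p_switch:
                    choices = [k for k in range(space.n_topics) if k != topic]
                    topic = int(choices[rng.integers(len(choices))])
                labels.append(topic)
                wlo, whi = profile.words_per_sentence
                n_words = int(rng.integers(wlo, whi + 1))
                words = []
                for _w in range(n_words):
                    u = rng.random()
                    if u < profile.stopword_rate and space.stopword_tokens:
                        words.append(
                            space.stopword_tokens[rng.integers(len(space.stopword_tokens))]
                        )
                    elif (
                        u < profile.stopword_rate + profile.filler_rate
                        and space.filler_tokens
                    ):
                        words.append(
                            space.filler_tokens[rng.integers(len(space.filler_tokens))]
                        )
                    else:
                        words.append(
                            space.topic_word(topic, int(rng.integers(space.vocab_per_topic)))
                        )
                words[0] = words[0].capitalize()
                sentence_texts.append(" ".join(words) + ".")
            answers.append(" ".join(sentence_texts))
        sections.append(
            EmotionSection(emotion=emotion, question_texts=questions, answer_texts=answers)
        )
        topic_labels[emotion] = labels
    return Transcript(participant_id=participant_id, sections=sections), topic_labels


@dataclass(frozen=True)
class OutcomeLink:
    """Linear-Gaussian link from standardized latent coherence to an outcome.

    outcome = mean + sd * (rho * z_latent + sqrt(1 - rho^2) * eps); the
    simplest structure that realizes a target Pearson rho. nonneg clips at
    zero (day counts), which mildly attenuates the realized correlation —
    the ground-truth table records the realized value.
    """

    name: str
    rho: float
    mean: float
    sd: float
    nonneg: bool = False

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1.0:
            raise ValueError(f"|rho| must be < 1, got {self.rho} for {self.name!r}")
        if self.sd <= 0:
            raise ValueError(f"sd must be positive for {self.name!r}")


#: default outcome links: marginal scales and effect magnitudes typical of
#: clinical validation cohorts (|rho| ~ 0.1-0.3)
DEFAULT_OUTCOME_LINKS = (
    OutcomeLink("panss_positive", -0.15, 13.34, 6.25),
    OutcomeLink("panss_negative", -0.31, 15.66, 6.86),
    OutcomeLink("panss_disorganized", -0.31, 16.87, 5.91),
    OutcomeLink("panss_excitement", -0.28, 12.62, 3.97),
    OutcomeLink("panss_emotional_distress", -0.13, 17.32, 5.85),
    OutcomeLink("mini_icf_sum", -0.21, 16.3, 9.34),
    OutcomeLink("onset_age", 0.0, 25.36, 7.63),
    OutcomeLink("illness_duration", 0.0, 13.47, 9.05),
    OutcomeLink("inpatient_days_2_5y_before", -0.09, 39.84, 68.43, nonneg=True),
    OutcomeLink("inpatient_days_0_5y_before", -0.25, 10.07, 34.39, nonneg=True),
    OutcomeLink("inpatient_days_0_5y_after", 0.11, 5.74, 16.16, nonneg=True),
)

DEFAULT_LONGITUDINAL = (
    "panss_positive",
    "panss_negative",
    "panss_disorganized",
    "panss_excitement",
    "panss_emotional_distress",
    "mini_icf_sum",
)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    Each participant's per-sentence topic-switch probability is drawn
    from Beta(*latent_beta*); the standardized negative of that switch
    rate is the latent coherence that outcomes are linked to. T2 outcome
    columns (suffix ``_t2``) follow an AR(1)-style link to their T1
    values with the stated autocorrelation.
    """

    n_participants: int
    seed: int
    latent_beta: tuple[float, float] = (1.5, 6.0)
    outcome_links: tuple[OutcomeLink, ...] = DEFAULT_OUTCOME_LINKS
    longitudinal_outcomes: tuple[str, ...] = DEFAULT_LONGITUDINAL
    longitudinal_autocorr: float = 0.7

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not -1.0 < self.longitudinal_autocorr < 1.0:
            raise ValueError("longitudinal autocorrelation must be in (-1, 1)")


@dataclass
class CohortResult:
    transcripts: list[Transcript]
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame  # per-participant latent values
    realized_links: pd.DataFrame  # per-outcome target vs realized rho


def generate_cohort(
    spec: CohortSpec,
    space: TopicSpace | None = None,
    profile: DriftProfile | None = None,
) -> CohortResult:
    """Generate transcripts + clinical table + ground truth for a cohort."""
    space = space or TopicSpace()
    profile = profile or DriftProfile()
    n = spec.n_participants
    ids = [f"S{i + 1:04d}" for i in range(n)]

    rng_latent = _stream(spec.seed, "cohort:latent")
    a, b = spec.latent_beta
    p_switch = rng_latent.beta(a, b, size=n)
    spread = p_switch.std(ddof=0)
    if spread == 0.0:  # single participant or degenerate draw
        z_latent = np.zeros(n)
    else:
        z_latent = -(p_switch - p_switch.mean()) / spread

    rng_out = _stream(spec.seed, "cohort:outcomes")
    clinical: dict[str, np.ndarray] = {"participant_id": np.asarray(ids, dtype=object)}
    z_by_outcome: dict[str, np.ndarray] = {}
    for link in spec.outcome_links:
        eps = rng_out.standard_normal(n)
        z = link.rho * z_latent + np.sqrt(1.0 - link.rho**2) * eps
        vals = link.mean + link.sd * z
        if link.nonneg:
            vals = np.clip(vals, 0.0, None)
        z_by_outcome[link.name] = z
        clinical[link.name] = vals

    rng_t2 = _stream(spec.seed, "cohort:t2")
    ac = spec.longitudinal_autocorr
    link_by_name = {lk.name: lk for lk in spec.outcome_links}
    for name in spec.longitudinal_outcomes:
        if name not in z_by_outcome:
            continue
        lk = link_by_name[name]
        z2 = ac * z_by_outcome[name] + np.sqrt(1.0 - ac**2) * rng_t2.standard_normal(n)
        vals = lk.mean + lk.sd * z2
        if lk.nonneg:
            vals = np.clip(vals, 0.0, None)
        clinical[name + "_t2"] = vals

    rng_cov = _stream(spec.seed, "cohort:covariates")
    clinical["age"] = np.clip(rng_cov.normal(38.8, 10.4, n), 18, 65)
    clinical["sex"] = np.where(rng_cov.random(n) < 0.634, "male", "female")
    clinical["education_years"] = np.clip(rng_cov.normal(15.3, 3.4, n), 8, 25)
    clinical["verbal_iq"] = rng_cov.normal(105.4, 12.2, n)
    clinical["medication"] = rng_cov.random(n) < 0.873

    transcript_seeds = _stream(spec.seed, "cohort:transcripts").integers(
        0, 2**31 - 1, size=n
    )
    transcripts = []
    for i, pid in enumerate(ids):
        p = DriftProfile(
            p_switch=float(p_switch[i]),
            within_topic_noise=profile.within_topic_noise,
            sentences_per_question=profile.sentences_per_question,
            words_per_sentence=profile.words_per_sentence,
            stopword_rate=profile.stopword_rate,
            filler_rate=profile.filler_rate,
        )
        t, _labels = generate_transcript(space, p, int(transcript_seeds[i]), pid)
        transcripts.append(t)

    clinical_df = pd.DataFrame(clinical)
    ground_truth = pd.DataFrame(
        {"participant_id": ids, "p_switch": p_switch, "latent_coherence_z": z_latent}
    )
    realized = []
    for link in spec.outcome_links:
        if n >= 3 and np.ptp(clinical[link.name]) > 0 and np.ptp(z_latent) > 0:
            realized_rho = float(np.corrcoef(z_latent, clinical[link.name])[0, 1])
        else:
            realized_rho = float("nan")
        realized.append(
            {"outcome": link.name, "target_rho": link.rho, "realized_rho": realized_rho}
        )
    return CohortResult(
        transcripts=transcripts,
        clinical=clinical_df,
        ground_truth=ground_truth,
        realized_links=pd.DataFrame(realized),
    )
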