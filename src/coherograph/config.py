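"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` fully determines a run: for fixed inputs and config
the pipeline is deterministic, and the emitted config snapshot reproduces
the run. Every output table carries the config hash in a leading
``# coherograph ...`` comment line.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .coherence import CoherenceConfig, score_cohort
from .embeddings import load_embeddings
from .preprocess import Lexicons, TableLemmatizer, identity_lemmatizer, preprocess_transcript
from .stats import read_clinical_table, render_report, validation_report
from .transcripts import annotate_transcript, read_transcript_dir

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {record!r}: {cause}")
        self.stage = stage
        self.record = record
        self.cause = cause


@dataclass
class RunConfig:
    transcripts_dir: str
    output_dir: str
    embeddings: list[dict] = field(default_factory=list)  # {name, path, dialect}
    clinical_path: str | None = None
    transcript_format: str = "structured"
    annotation_mode: str = "marker"
    local_denominator: str = "pairs"
    global_denominator: str = "terms"
    aggregation: str = "section"
    t_test_equal_var: bool = False
    oov_lowercase_fallback: bool = True
    stopword_file: str | None = None
    filler_file: str | None = None
    conjunction_file: str | None = None
    lemmatizer: str = "identity"  # "identity" | "table:<path>"
    seed: int = 0
    version: str = __version__

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (CLI flags) take precedence."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> list[str]:
        """Fail-fast checks before any computation; returns problem list."""
        problems = []
        if not Path(self.transcripts_dir).is_dir():
            problems.append(f"transcripts_dir does not exist: {self.transcripts_dir}")
        if not self.embeddings:
            problems.append("no embedding models configured")
        for spec in self.embeddings:
            if "path" not in spec or "name" not in spec:
                problems.append(f"embedding entry needs name and path: {spec}")
            elif not Path(spec["path"]).is_file():
                problems.append(f"embedding file does not exist: {spec['path']}")
        if self.clinical_path and not Path(self.clinical_path).is_file():
            problems.append(f"clinical table does not exist: {self.clinical_path}")
        if self.lemmatizer != "identity" and not self.lemmatizer.startswith("table:"):
            problems.append(f"unknown lemmatizer spec: {self.lemmatizer!r}")
        try:
            CoherenceConfig(
                self.local_denominator, self.global_denominator, self.aggregation
            )
        except ValueError as e:
            problems.append(str(e))
        return problems


def _write_table(df, path: Path, cfg_hash: str) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# coherograph {__version__} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute ingest -> annotate -> preprocess -> score -> validate.

    Writes to the output directory: scores.csv, report_*.csv and
    report.txt (when a clinical table is given), run_config.yaml, run.log.
    Returns the output directory path.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid run configuration: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log_lines = [f"coherograph {__version__} config_hash={cfg_hash}"]

    try:
        transcripts = read_transcript_dir(config.transcripts_dir, config.transcript_format)
    except Exception as e:
        raise PipelineError("ingest", config.transcripts_dir, e) from e
    if not transcripts:
        raise ValueError(f"no transcripts found in {config.transcripts_dir}")

    lexicons = Lexicons.from_files(
        config.filler_file, config.stopword_file, config.conjunction_file
    )
    if config.lemmatizer == "identity":
        lemmatizer = identity_lemmatizer
    else:
        lemmatizer = TableLemmatizer.from_file(config.lemmatizer.split(":", 1)[1])

    preprocessed = []
    for t in transcripts:
        try:
            annotated = annotate_transcript(t, config.annotation_mode)
            pt = preprocess_transcript(annotated, lexicons, lemmatizer)
        except Exception as e:
            raise PipelineError("preprocess", t.participant_id, e) from e
        preprocessed.append(pt)
        log_lines.append(
            f"participant {pt.participant_id}: words={pt.word_count} "
            f"unique={pt.unique_word_count} processed={pt.processed_word_count}"
        )

    models = []
    for spec in config.embeddings:
        try:
            model = load_embeddings(
                spec["path"], spec.get("dialect", "auto"), name=spec["name"]
            )
        except Exception as e:
            raise PipelineError("load_embeddings", spec["name"], e) from e
        model.lowercase_fallback = config.oov_lowercase_fallback
        models.append(model)

    coherence_cfg = CoherenceConfig(
        config.local_denominator, config.global_denominator, config.aggregation
    )
    try:
        scores = score_cohort(preprocessed, models, coherence_cfg)
    except Exception as e:
        raise PipelineError("score", "cohort", e) from e
    _write_table(scores, out / "scores.csv", cfg_hash)
    for model in models:
        used = scores[f"sentences_used_{model.name}"].sum()
        log_lines.append(f"model {model.name}: total sentences used={int(used)}")

    if config.clinical_path:
        try:
            clinical = read_clinical_table(config.clinical_path)
            bundle = validation_report(
                scores, clinical, equal_var=config.t_test_equal_var
            )
        except Exception as e:
            raise PipelineError("validate", str(config.clinical_path), e) from e
        _write_table(bundle.correlations, out / "report_correlations.csv", cfg_hash)
        _write_table(
            bundle.partial_longitudinal, out / "report_partial_longitudinal.csv", cfg_hash
        )
        _write_table(bundle.t_tests, out / "report_t_tests.csv", cfg_hash)
        _write_table(bundle.controls_screen, out / "report_controls_screen.csv", cfg_hash)
        (out / "report.txt").write_text(
            f"# coherograph {__version__} config_hash={cfg_hash}\n"
            + render_report(bundle)
            + "\n",
            encoding="utf-8",
        )
        log_lines.append(
            f"validation join: n={bundle.join_report['n_joined']} "
            f"scores_only={len(bundle.join_report['scores_only'])} "
            f"clinical_only={len(bundle.join_report['clinical_only'])}"
        )

    config.to_yaml(out / "run_config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
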