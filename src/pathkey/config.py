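"""End-to-end pipeline: configuration validation, staged execution, and a
reproducibility manifest.

All randomness flows from one config seed through named substreams (corpus
generation, train/test split, model initialization, NSP pairing), so a full
run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, PathkeyError
from .evaluation import MetricsReport, evaluate_extractions
from .preprocessing import Statement, SubwordVocabulary, align_labels, \
    normalize, tokenize_statement, train_wordpiece_vocabulary
from .synthetic import CorpusConfig, Report, generate_corpus, \
    iter_statements, read_jsonl, train_test_split, write_jsonl
from .taggers import TrainConfig, train_bayes, train_neural, save_model

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "seed_streams", "prepare_statements"]

logger = logging.getLogger(__name__)

_SUBSTREAMS = ("corpus", "split", "init", "typos", "nsp")


def seed_streams(seed: int) -> dict[str, int]:
    """Named integer sub-seeds derived from one root seed (all < 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_SUBSTREAMS, children)}


@dataclass
class PipelineConfig:
    """One JSON document drives a full run."""

    out_dir: str = "pathkey_run"
    corpus_path: str | None = None      # existing JSONL; None -> synthesize
    n_reports: int = 500                # synthesis size when generating
    vocab_path: str | None = None       # existing vocabulary file
    vocab_size: int = 2000
    model: str = "bayes"                # bayes | recurrent | convolutional
    #                                     | transformer-adapter
    train_fraction: float = 0.9
    test_fraction: float = 0.1
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violation; an empty list means the config is valid."""
    errors: list[str] = []
    if abs(config.train_fraction + config.test_fraction - 1.0) > 1e-9:
        errors.append(
            f"split fractions must sum to 1: train_fraction="
            f"{config.train_fraction}, test_fraction={config.test_fraction}")
    if not 0.0 <= config.test_fraction <= 1.0:
        errors.append(f"test_fraction={config.test_fraction} outside [0,1]")
    if config.corpus_path is not None and not Path(config.corpus_path).exists():
        errors.append(f"corpus_path does not exist: {config.corpus_path}")
    if config.vocab_path is not None and not Path(config.vocab_path).exists():
        errors.append(f"vocab_path does not exist: {config.vocab_path}")
    if config.model not in ("bayes", "recurrent", "convolutional",
                            "transformer-adapter"):
        errors.append(f"unknown model {config.model!r}")
    if config.corpus_path is None and config.n_reports < 1:
        errors.append(f"n_reports={config.n_reports} must be positive")
    if config.epochs < 0:
        errors.append(f"epochs={config.epochs} must be >= 0")
    if config.vocab_path is None and config.vocab_size < 1:
        errors.append(f"vocab_size={config.vocab_size} must be positive")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def prepare_statements(reports: list[Report], vocab: SubwordVocabulary):
    """Normalize, align and tokenize every statement of every report.

    Returns tagged TokenizedStatements; also verifies that re-splitting each
    report's text yields the recorded statements.
    """
    tokenized = []
    for stmt_id, text, gold in iter_statements(reports):
        words = tuple(normalize(text))
        tags = align_labels(words, gold, statement_id=stmt_id)
        st = Statement(statement_id=stmt_id, raw_text=text, words=words,
                       gold=gold)
        tokenized.append(tokenize_statement(st, vocab, tags=tags))
    return tokenized


def run_pipeline(config: PipelineConfig):
    """synthesize (optional) -> preprocess -> train -> extract -> evaluate.

    Writes corpus, vocabulary, model bundle, extraction JSONL, metrics JSON
    and a manifest with content hashes into ``config.out_dir``. Returns
    (MetricsReport, list of ExtractionResult).
    """
    errors = validate_config(config)
    if errors:
        raise ConfigurationError("; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = seed_streams(config.seed)
    stage = "synthesize"
    try:
        if config.corpus_path is None:
            reports = generate_corpus(CorpusConfig(
                n_reports=config.n_reports, seed=seeds["corpus"]))
            corpus_path = out / "corpus.jsonl"
            write_jsonl(reports, corpus_path)
        else:
            corpus_path = Path(config.corpus_path)
            reports = read_jsonl(corpus_path)

        stage = "preprocess"
        if config.vocab_path is not None:
            vocab = SubwordVocabulary.load(config.vocab_path)
            vocab_path = Path(config.vocab_path)
        else:
            all_words = [w for _, text, _ in iter_statements(reports)
                         for w in normalize(text)]
            vocab = train_wordpiece_vocabulary(all_words,
                                               size=config.vocab_size)
            vocab_path = out / "vocab.txt"
            vocab.save(vocab_path)
        tokenized = prepare_statements(reports, vocab)
        train_set, test_set = train_test_split(
            tokenized, test_fraction=config.test_fraction,
            seed=seeds["split"])

        stage = "train"
        if config.model == "bayes":
            model = train_bayes(train_set)
        else:
            arch = ("transformer-adapter"
                    if config.model == "transformer-adapter"
                    else config.model)
            model = train_neural(
                train_set, architecture=arch,
                config=TrainConfig(epochs=config.epochs,
                                   batch_size=config.batch_size,
                                   learning_rate=config.learning_rate,
                                   seed=seeds["init"]))
        model_dir = out / "model"
        save_model(model, model_dir, vocab=vocab)

        stage = "evaluate"
        if not test_set:
            logger.info("test fraction is 0; evaluation stage skipped")
            report_obj, results = MetricsReport(), []
            eval_set = []
        else:
            eval_set = test_set
            report_obj, results = evaluate_extractions(model, eval_set)

        stage = "write-outputs"
        extracted_path = out / "extracted.jsonl"
        with extracted_path.open("w", encoding="utf-8") as fh:
            for res in results:
                fh.write(json.dumps(res.as_dict()) + "\n")
        metrics_path = out / "metrics.json"
        metrics_path.write_text(
            json.dumps(report_obj.as_dict(), indent=2), encoding="utf-8")

        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "substream_seeds": seeds,
            "n_reports": len(reports),
            "n_statements": len(tokenized),
            "n_train": len(train_set),
            "n_test": len(test_set),
            "hashes": {
                "corpus": _sha256(corpus_path),
                "vocab": _sha256(vocab_path),
                "extracted": _sha256(extracted_path),
                "metrics": _sha256(metrics_path),
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8")
        return report_obj, results
    except PathkeyError:
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        raise PathkeyError(f"pipeline stage {stage!r} failed: {exc}") from exc
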