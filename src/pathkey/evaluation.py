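"""Extraction metrics and experiment harnesses.

Precision/recall/F1 are computed at word level (the taggers classify each
word), micro-averaged over all words of all statements. Exact matching is
stricter: the fraction of statements whose assembled keyword string for a
type equals the normalized gold string character for character. Cross-
entropy is the mean token loss used for training, recomputed overflow-safe.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .classes import CLASSES, KEYWORD_TYPES, N_CLASSES
from .decoding import ExtractionResult, extract_statement
from .errors import ConfigurationError, EvaluationError
from .preprocessing import TokenizedStatement, normalize
from .synthetic import GoldAnnotation
from .taggers import TrainConfig, train_neural

__all__ = ["ClassMetrics", "MetricsReport", "word_prf", "exact_match_rate",
           "cross_entropy", "run_ablation", "AblationResult",
           "evaluate_extractions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    predicted: int
    precision_defined: bool = True
    recall_defined: bool = True


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)
    exact_matching: dict[str, float] = field(default_factory=dict)
    mean_cross_entropy: float | None = None
    n_statements: int = 0

    def as_dict(self) -> dict:
        out: dict = {"n_statements": self.n_statements}
        for cls, m in self.per_class.items():
            out[cls] = {"precision": m.precision, "recall": m.recall,
                        "f1": m.f1, "support": m.support,
                        "predicted": m.predicted,
                        "precision_defined": m.precision_defined,
                        "recall_defined": m.recall_defined}
        out["exact_matching"] = dict(self.exact_matching)
        if self.mean_cross_entropy is not None:
            out["mean_cross_entropy"] = self.mean_cross_entropy
        return out

    def micro_keyword_f1(self) -> float:
        """Micro F1 pooled over the three keyword classes (not O)."""
        tp = fp = fn = 0
        for cls in CLASSES[:3]:
            m = self.per_class[cls]
            tp_c = round(m.recall * m.support)
            tp += tp_c
            fn += m.support - tp_c
            fp += m.predicted - tp_c
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        return 2 * p * r / (p + r) if p + r else 0.0


def word_prf(
    predicted: Sequence[Sequence[int]],
    gold: Sequence[Sequence[int]],
) -> dict[str, ClassMetrics]:
    """Micro-averaged per-class precision/recall/F1 over word classes.

    ``predicted`` and ``gold`` are parallel per-statement class-index
    sequences. Undefined ratios (empty denominator) are reported as 0 with
    the corresponding ``*_defined`` flag cleared.
    """
    if len(predicted) != len(gold):
        raise EvaluationError(
            f"{len(predicted)} predicted vs {len(gold)} gold statements")
    tp = np.zeros(N_CLASSES, dtype=np.int64)
    fp = np.zeros(N_CLASSES, dtype=np.int64)
    fn = np.zeros(N_CLASSES, dtype=np.int64)
    for i, (p_seq, g_seq) in enumerate(zip(predicted, gold)):
        if len(p_seq) != len(g_seq):
            raise EvaluationError(
                f"statement {i}: {len(p_seq)} predicted vs "
                f"{len(g_seq)} gold words")
        p = np.asarray(p_seq, dtype=np.int64)
        g = np.asarray(g_seq, dtype=np.int64)
        for c in range(N_CLASSES):
            tp[c] += int(((p == c) & (g == c)).sum())
            fp[c] += int(((p == c) & (g != c)).sum())
            fn[c] += int(((p != c) & (g == c)).sum())
    out = {}
    for c, name in enumerate(CLASSES):
        p_den = tp[c] + fp[c]
        r_den = tp[c] + fn[c]
        prec = tp[c] / p_den if p_den else 0.0
        rec = tp[c] / r_den if r_den else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[name] = ClassMetrics(
            precision=float(prec), recall=float(rec), f1=float(f1),
            support=int(r_den), predicted=int(p_den),
            precision_defined=bool(p_den), recall_defined=bool(r_den))
    return out


def _normalize_string(s: str) -> str:
    return " ".join(normalize(s))


def exact_match_rate(
    results: Iterable[ExtractionResult],
    golds: Mapping[str, GoldAnnotation],
) -> dict[str, float]:
    """Per-type fraction of statements whose extracted keyword string
    equals the normalized gold string exactly (order-sensitive)."""
    results = list(results)
    if not results:
        raise EvaluationError("no extraction results to evaluate")
    hits = dict.fromkeys(KEYWORD_TYPES, 0)
    for res in results:
        if res.statement_id not in golds:
            raise EvaluationError(
                f"no gold annotation for statement {res.statement_id!r}")
        gold = golds[res.statement_id]
        for t in KEYWORD_TYPES:
            if (_normalize_string(res.keyword(t))
                    == _normalize_string(getattr(gold, t))):
                hits[t] += 1
    return {t: hits[t] / len(results) for t in KEYWORD_TYPES}


def cross_entropy(
    token_logits: np.ndarray,
    token_tags: Sequence[int],
) -> float:
    """Mean over tokens of -log softmax(p_ij)[gold class], overflow-safe."""
    logits = np.asarray(token_logits, dtype=float)
    tags = np.asarray(token_tags, dtype=np.int64)
    if logits.shape[0] != len(tags):
        raise EvaluationError(
            f"{logits.shape[0]} score rows vs {len(tags)} tags")
    if logits.shape[0] == 0:
        raise EvaluationError("cannot average a loss over zero tokens")
    lse = logsumexp(logits, axis=1)
    picked = logits[np.arange(len(tags)), tags]
    return float(np.mean(lse - picked))


def evaluate_extractions(
    model,
    statements: Sequence[TokenizedStatement],
) -> tuple[MetricsReport, list[ExtractionResult]]:
    """Tag, decode and score a set of gold-annotated statements."""
    predicted_classes: list[Sequence[int]] = []
    gold_classes: list[Sequence[int]] = []
    results: list[ExtractionResult] = []
    golds: dict[str, GoldAnnotation] = {}
    losses: list[float] = []
    n_tokens = 0
    for st in statements:
        res = extract_statement(model, st)
        results.append(res)
        golds[st.statement_id] = st.gold or GoldAnnotation()
        predicted_classes.append(res.word_classes)
        gold_classes.append(st.word_tags())
        if st.token_tags is not None and len(st.tokens):
            logits = model.predict_logits(st.tokens)
            losses.append(cross_entropy(logits, st.token_tags)
                          * len(st.tokens))
            n_tokens += len(st.tokens)
    report = MetricsReport(
        per_class=word_prf(predicted_classes, gold_classes),
        exact_matching=exact_match_rate(results, golds),
        mean_cross_entropy=(sum(losses) / n_tokens if n_tokens else None),
        n_statements=len(results))
    return report, results


def epochs_to_f1_threshold(
    initial_model,
    train_statements: Sequence[TokenizedStatement],
    test_statements: Sequence[TokenizedStatement],
    threshold: float = 0.7,
    max_epochs: int = 15,
    learning_rate: float | None = None,
    batch_size: int = 16,
    seed: int = 0,
) -> tuple[int, float]:
    """Fine-tune epoch by epoch until the test micro keyword F1 reaches
    ``threshold``; returns (epochs used, last F1). When the threshold is not
    reached within ``max_epochs``, returns (max_epochs + 1, last F1).

    Used to compare a pre-trained encoder against a randomly initialized
    one: pre-training helps when it reaches the threshold in no more
    epochs.
    """
    model = initial_model
    f1 = 0.0
    for epoch in range(1, max_epochs + 1):
        cfg = TrainConfig(epochs=1, seed=seed + epoch,
                          batch_size=batch_size,
                          learning_rate=learning_rate)
        model = train_neural(train_statements, config=cfg,
                             initial_model=model)
        report, _ = evaluate_extractions(model, test_statements)
        f1 = report.micro_keyword_f1()
        if f1 >= threshold:
            return epoch, f1
    return max_epochs + 1, f1


@dataclass(frozen=True)
class AblationRow:
    training_size: int
    epoch: int
    keyword_type: str
    exact_matching: float


@dataclass
class AblationResult:
    rows: list[AblationRow] = field(default_factory=list)

    def final(self, training_size: int, keyword_type: str) -> float:
        """Exact matching at the last recorded epoch for one setting."""
        matching = [r for r in self.rows
                    if r.training_size == training_size
                    and r.keyword_type == keyword_type]
        if not matching:
            raise KeyError((training_size, keyword_type))
        return max(matching, key=lambda r: r.epoch).exact_matching

    def to_tsv(self, path) -> None:
        from pathlib import Path
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("size\tepoch\ttype\texact_matching\n")
            for r in self.rows:
                fh.write(f"{r.training_size}\t{r.epoch}\t"
                         f"{r.keyword_type}\t{r.exact_matching:.6f}\n")


def run_ablation(
    train_statements: Sequence[TokenizedStatement],
    test_statements: Sequence[TokenizedStatement],
    sizes: Sequence[int] = (100, 300, 500, 1000, 3000),
    epochs: int = 5,
    architecture: str = "recurrent",
    vocab=None,
    seed: int = 0,
    model_kwargs: dict | None = None,
    batch_size: int = 16,
) -> AblationResult:
    """Train from scratch on size-limited subsamples; record per-epoch
    exact matching per type on a fixed test split."""
    result = AblationResult()
    rng = np.random.default_rng(seed)
    for size in sizes:
        if size > len(train_statements):
            raise ConfigurationError(
                f"ablation size {size} exceeds corpus size "
                f"{len(train_statements)}")
        subsample_idx = rng.choice(len(train_statements), size=size,
                                   replace=False)
        subsample = [train_statements[int(i)] for i in subsample_idx]
        model = None
        for epoch in range(1, epochs + 1):
            cfg = TrainConfig(epochs=1, seed=seed, batch_size=batch_size)
            model = train_neural(
                subsample, architecture=architecture, config=cfg,
                vocab=vocab, initial_model=model,
                model_kwargs=model_kwargs)
            report, _ = evaluate_extractions(model, test_statements)
            for t in KEYWORD_TYPES:
                result.rows.append(AblationRow(
                    training_size=size, epoch=epoch, keyword_type=t,
                    exact_matching=report.exact_matching[t]))
    return result
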