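"""Token taggers: a naive Bayes baseline, small trainable neural taggers,
and next-statement-prediction (NSP) pre-training.

All taggers share one prediction contract: given the subword tokens of a
statement they return a ``(n_tokens, 4)`` array of pre-softmax class scores
p_ij^l in the fixed class order (SPE, PRO, PAT, O). The Bayes model emits
smoothed log-probabilities in that slot so the downstream word-level
aggregation applies uniformly to every model.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from collections import deque
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classes import CLASSES, N_CLASSES, O_INDEX
from .errors import CapabilityError, ConfigurationError
from .networks import Adam, ConvTagger, NeuralTagger, RecurrentTagger, \
    TransformerTagger
from .preprocessing import SubwordVocabulary, TokenizedStatement

__all__ = [
    "BayesModel", "train_bayes", "predict", "TrainConfig", "train_neural",
    "NSPPair", "make_nsp_corpus", "pretrain_nsp", "NSPResult",
    "save_model", "load_model", "ARCHITECTURES",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = {
    "recurrent": RecurrentTagger,
    "convolutional": ConvTagger,
    "transformer-adapter": TransformerTagger,
}


# --------------------------------------------------------------------------
# Naive Bayes baseline
# --------------------------------------------------------------------------

@dataclass
class BayesModel:
    """Token-identity naive Bayes with Laplace smoothing.

    Scores are ``log[(count(t,l)+a) / (count(l)+a*V)] + log prior(l)`` with
    pseudo-count ``a`` and V distinct training tokens. Priors are smoothed
    the same way so a class absent from training keeps a finite score.
    """

    smoothing: float = 1.0
    class_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CLASSES))
    token_class_counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def vocab_size(self) -> int:
        return len(self.token_class_counts)

    def _log_prior(self) -> np.ndarray:
        a = self.smoothing
        total = self.class_counts.sum()
        return np.log((self.class_counts + a) / (total + N_CLASSES * a))

    def predict_logits(self, tokens: Sequence[str]) -> np.ndarray:
        a = self.smoothing
        V = max(self.vocab_size, 1)
        denom = self.class_counts + a * V
        log_prior = self._log_prior()
        zeros = np.zeros(N_CLASSES)
        out = np.empty((len(tokens), N_CLASSES))
        for i, tok in enumerate(tokens):
            counts = self.token_class_counts.get(tok, zeros)
            out[i] = np.log((counts + a) / denom) + log_prior
        return out

    # TSV serialization: token, class tag, count
    def save_counts(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for tok in sorted(self.token_class_counts):
                for c, n in enumerate(self.token_class_counts[tok]):
                    if n:
                        fh.write(f"{tok}\t{CLASSES[c]}\t{int(n)}\n")

    @classmethod
    def load_counts(cls, path: str | Path,
                    smoothing: float = 1.0) -> "BayesModel":
        model = cls(smoothing=smoothing)
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            tok, tag, n = line.split("\t")
            c = CLASSES.index(tag)
            vec = model.token_class_counts.setdefault(
                tok, np.zeros(N_CLASSES))
            vec[c] += int(n)
            model.class_counts[c] += int(n)
        return model


def train_bayes(
    statements: Iterable[TokenizedStatement],
    smoothing: float = 1.0,
) -> BayesModel:
    """Count (token, class) pairs over tagged statements."""
    if smoothing <= 0:
        raise ConfigurationError("smoothing pseudo-count must be > 0")
    model = BayesModel(smoothing=smoothing)
    n_statements = 0
    for st in statements:
        if st.token_tags is None:
            raise ValueError(f"statement {st.statement_id} is untagged")
        n_statements += 1
        for tok, tag in zip(st.tokens, st.token_tags):
            vec = model.token_class_counts.setdefault(
                tok, np.zeros(N_CLASSES))
            vec[tag] += 1
            model.class_counts[tag] += 1
    if n_statements == 0:
        raise ConfigurationError("train_bayes requires >= 1 statement")
    if model.class_counts[:O_INDEX].sum() == 0:
        warnings.warn("training data contains no keyword tags; "
                      "the Bayes model will predict O everywhere")
    return model


def predict(model, statement: TokenizedStatement) -> np.ndarray:
    """Per-token class scores p_ij^l for any trained tagger."""
    return model.predict_logits(statement.tokens)


# --------------------------------------------------------------------------
# Neural training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings.

    ``learning_rate=None`` selects the per-architecture default: 1e-3 for
    the small from-scratch taggers, 2e-5 for the full-scale transformer
    preset (a fine-tuning rate tuned for pre-trained weights).
    """

    learning_rate: float | None = None
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")


_DEFAULT_LR = {"recurrent": 1e-3, "convolutional": 1e-3,
               "transformer": 1e-3}


def train_neural(
    statements: Sequence[TokenizedStatement],
    architecture: str = "recurrent",
    config: TrainConfig | None = None,
    vocab: SubwordVocabulary | None = None,
    initial_model: NeuralTagger | None = None,
    model_kwargs: dict | None = None,
) -> NeuralTagger:
    """Train a token tagger by minimizing per-token cross-entropy.

    With ``epochs=0`` the freshly initialized (or copied) model is returned
    untouched. ``initial_model`` continues from existing weights, e.g. an
    NSP-pre-trained encoder. Per-epoch mean training loss is recorded on
    ``model.history``.
    """
    config = config or TrainConfig()
    if initial_model is not None:
        model = copy.deepcopy(initial_model)
    else:
        if architecture not in ARCHITECTURES:
            raise CapabilityError(
                f"unknown architecture {architecture!r}; available: "
                f"{sorted(ARCHITECTURES)}")
        if vocab is None:
            raise ConfigurationError(
                "a SubwordVocabulary is required to build a new tagger")
        cls = ARCHITECTURES[architecture]
        model = cls(vocab.entries, seed=config.seed,
                    **(model_kwargs or {}))
    tagged = [st for st in statements if len(st.tokens) > 0]
    if any(st.token_tags is None for st in tagged):
        raise ValueError("all statements must carry token tags")
    if not tagged:
        raise ConfigurationError("no non-empty statements to train on")

    lr = config.learning_rate or _DEFAULT_LR.get(model.architecture, 1e-3)
    opt = Adam(model.params, lr=lr)
    rng = np.random.default_rng(config.seed)
    n = len(tagged)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [tagged[i] for i in order[start:start +
                                              config.batch_size]]
            X, mask = model.pad_batch([st.tokens for st in batch])
            Y = np.zeros(X.shape, dtype=np.int64)
            for b, st in enumerate(batch):
                Y[b, :len(st.token_tags)] = st.token_tags
            loss, grads = model.loss_and_grads(X, mask, Y)
            opt.step(grads)
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    return model


# --------------------------------------------------------------------------
# Next-statement-prediction pre-training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NSPPair:
    """A sentence pair labeled IsNext (adjacent in one report) or NotNext."""

    first: tuple[str, ...]
    second: tuple[str, ...]
    label: str  # "IsNext" | "NotNext"

    def __post_init__(self) -> None:
        if not self.first or not self.second:
            raise ValueError("NSP segments must be non-empty")
        if self.label not in ("IsNext", "NotNext"):
            raise ValueError(f"bad NSP label {self.label!r}")

    @property
    def is_next(self) -> bool:
        return self.label == "IsNext"


def make_nsp_corpus(
    report_token_seqs: Sequence[Sequence[Sequence[str]]],
    n_pairs: int,
    seed: int = 0,
) -> list[NSPPair]:
    """Build a sentence-pair corpus with a constructive 1:2 label ratio.

    ``report_token_seqs`` holds, per report, the ordered token sequences of
    its statements. IsNext pairs are adjacent statements of one report;
    NotNext pairs are random non-adjacent selections. Exactly one third of
    the pairs (rounded as (n+1)//3) is IsNext. Deterministic under ``seed``.
    """
    if n_pairs < 3:
        raise ConfigurationError("n_pairs must be >= 3")
    flat: list[tuple[int, int, tuple[str, ...]]] = []
    adjacent: list[tuple[int, int]] = []
    for r, stmts in enumerate(report_token_seqs):
        stmts = [tuple(s) for s in stmts if len(s) > 0]
        for k, toks in enumerate(stmts):
            flat.append((r, k, toks))
        for k in range(len(stmts) - 1):
            adjacent.append((len(flat) - len(stmts) + k,
                             len(flat) - len(stmts) + k + 1))
    if len(flat) < 2:
        raise ConfigurationError("need at least 2 statements for NSP pairs")
    if not adjacent:
        raise ConfigurationError(
            "no report has two consecutive statements; "
            "IsNext pairs cannot be formed")
    adjacent_set = set(adjacent)
    rng = np.random.default_rng(seed)
    n_is = (n_pairs + 1) // 3
    pairs: list[NSPPair] = []
    for i in rng.integers(0, len(adjacent), size=n_is):
        a, b = adjacent[int(i)]
        pairs.append(NSPPair(flat[a][2], flat[b][2], "IsNext"))
    while len(pairs) < n_pairs:
        a = int(rng.integers(len(flat)))
        b = int(rng.integers(len(flat)))
        if a == b or (a, b) in adjacent_set or (b, a) in adjacent_set:
            continue
        pairs.append(NSPPair(flat[a][2], flat[b][2], "NotNext"))
    order = rng.permutation(n_pairs)
    return [pairs[int(i)] for i in order]


@dataclass
class NSPResult:
    steps: int
    accuracy: float
    reached: bool


def pretrain_nsp(
    tagger: NeuralTagger,
    pairs: Sequence[NSPPair],
    accuracy_threshold: float = 0.99,
    max_steps: int = 20000,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    window_batches: int = 50,
    max_segment_tokens: int = 32,
    update: str = "encoder",
) -> tuple[NeuralTagger, NSPResult]:
    """Pre-train a tagger's encoder on the binary IsNext/NotNext task.

    Each segment is encoded by the tagger (masked mean of token states);
    a logistic head over [h_a, h_b, h_a*h_b, |h_a-h_b|] classifies the
    pair. Training stops when the running accuracy over the last
    ``window_batches`` mini-batches reaches the threshold, or at
    ``max_steps``. The head is discarded; the encoder (all parameters
    except the tagging head) keeps its trained weights.
    """
    if not 0.0 <= accuracy_threshold <= 1.0:
        raise ConfigurationError("accuracy_threshold must be in [0, 1]")
    if not pairs:
        raise ConfigurationError("no NSP pairs supplied")
    if update not in ("encoder", "embedding"):
        raise ConfigurationError(
            f"update must be 'encoder' or 'embedding', got {update!r}")
    tagger = copy.deepcopy(tagger)
    rng = np.random.default_rng(seed)
    h = tagger.state_dim
    head = {"Wn": rng.normal(0, 1 / np.sqrt(4 * h), (4 * h,)),
            "bn": np.zeros(1)}
    enc_names = (tagger.encoder_param_names() if update == "encoder"
                 else ("E",))
    enc_params = {k: tagger.params[k] for k in enc_names}
    opt = Adam({**enc_params, **head}, lr=learning_rate)

    recent: deque[np.ndarray] = deque(maxlen=window_batches)
    step = 0
    accuracy = 0.0
    order = rng.permutation(len(pairs))
    cursor = 0
    while step < max_steps:
        if cursor + batch_size > len(pairs):
            order = rng.permutation(len(pairs))
            cursor = 0
        batch = [pairs[int(i)] for i in order[cursor:cursor + batch_size]]
        cursor += batch_size
        step += 1

        seg_a = [p.first[:max_segment_tokens] for p in batch]
        seg_b = [p.second[:max_segment_tokens] for p in batch]
        y = np.array([1.0 if p.is_next else 0.0 for p in batch])
        Xa, ma = tagger.pad_batch(seg_a)
        Xb, mb = tagger.pad_batch(seg_b)
        ha, cache_a = tagger.encode_mean(Xa, ma)
        hb, cache_b = tagger.encode_mean(Xb, mb)
        feats = np.concatenate([ha, hb, ha * hb, np.abs(ha - hb)], axis=1)
        logit = feats @ head["Wn"] + head["bn"][0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        correct = (prob >= 0.5) == (y >= 0.5)
        recent.append(correct)

        dlogit = (prob - y) / len(batch)
        grads = {"Wn": feats.T @ dlogit,
                 "bn": np.array([dlogit.sum()])}
        dfeats = dlogit[:, None] * head["Wn"][None, :]
        dha = (dfeats[:, :h] + dfeats[:, 2 * h:3 * h] * hb
               + dfeats[:, 3 * h:] * np.sign(ha - hb))
        dhb = (dfeats[:, h:2 * h] + dfeats[:, 2 * h:3 * h] * ha
               - dfeats[:, 3 * h:] * np.sign(ha - hb))
        for g in (tagger.backward_encode_mean(cache_a, dha),
                  tagger.backward_encode_mean(cache_b, dhb)):
            for k, v in g.items():
                if k in grads:
                    grads[k] = grads[k] + v
                else:
                    grads[k] = v
        opt.step(grads)

        accuracy = float(np.concatenate(list(recent)).mean())
        if accuracy >= accuracy_threshold:
            return tagger, NSPResult(step, accuracy, True)

    warnings.warn(
        f"NSP pre-training stopped at max_steps={max_steps} with running "
        f"accuracy {accuracy:.4f} < threshold {accuracy_threshold}")
    return tagger, NSPResult(step, accuracy, False)


# --------------------------------------------------------------------------
# Model bundle serialization
# --------------------------------------------------------------------------

def save_model(model, directory: str | Path,
               vocab: SubwordVocabulary | None = None) -> None:
    """Write a single-directory bundle: config JSON + weights/counts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, BayesModel):
        cfg = {"kind": "bayes", "smoothing": model.smoothing}
        model.save_counts(directory / "counts.tsv")
    else:
        cfg = {"kind": "neural", "architecture": model.architecture,
               "state_dim": model.state_dim,
               "id_of": model.id_of, "seed": model.seed}
        np.savez(directory / "weights.npz", **model.params)
    (directory / "config.json").write_text(json.dumps(cfg), "utf-8")
    if vocab is not None:
        vocab.save(directory / "vocab.txt")


def load_model(directory: str | Path):
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text("utf-8"))
    if cfg["kind"] == "bayes":
        return BayesModel.load_counts(directory / "counts.tsv",
                                      smoothing=cfg["smoothing"])
    arch = cfg["architecture"]
    cls = {"recurrent": RecurrentTagger, "convolutional": ConvTagger,
           "transformer": TransformerTagger}[arch]
    entries = [t for t, _ in sorted(cfg["id_of"].items(),
                                    key=lambda kv: kv[1])]
    model = cls(entries, seed=cfg.get("seed", 0))
    with np.load(directory / "weights.npz") as data:
        for k in model.params:
            model.params[k] = data[k]
    model.state_dim = model.params["Wo"].shape[0]
    return model
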