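"""Detokenization: word-level class probabilities from token scores, and
keyword-string assembly.

A word w_i split into tokens t_i1..t_iJ receives the class distribution

    w_i^l = sum_j exp(p_ij^l) / sum_j sum_{l'} exp(p_ij^{l'})

where p_ij^l are the model's pre-softmax token scores. For J=1 this reduces
to the softmax of the single token's scores. The implementation subtracts
the per-word maximum score before exponentiation, which is algebraically
exact and avoids overflow.

The word class is argmax_l w_i^l, ties broken by the fixed class order
(SPE, PRO, PAT, O): the first maximum wins. Per keyword type, the words
assigned that class are joined in text order into the type's keyword string.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .classes import CLASSES, CLASS_TO_INDEX, N_CLASSES
from .preprocessing import TokenizedStatement

__all__ = [
    "WordProbabilities",
    "ExtractionResult",
    "aggregate_word_probs",
    "assign_word_classes",
    "assemble_keywords",
    "extract_statement",
]

#: Word-level probabilities are an (n_words, 4) array; rows sum to 1.
WordProbabilities = np.ndarray


@dataclass(frozen=True)
class ExtractionResult:
    """Per-statement keyword strings and the word classes behind them."""

    statement_id: str
    specimen: str
    procedure: str
    pathology: str
    word_classes: tuple[int, ...]

    def keyword(self, keyword_type: str) -> str:
        return getattr(self, keyword_type)

    def as_dict(self) -> dict:
        return {
            "statement_id": self.statement_id,
            "specimen": self.specimen,
            "procedure": self.procedure,
            "pathology": self.pathology,
            "word_classes": [CLASSES[c] for c in self.word_classes],
        }


def aggregate_word_probs(
    token_logits: np.ndarray,
    word_index: Sequence[int],
    n_words: int | None = None,
) -> WordProbabilities:
    """Aggregate per-token scores into per-word class probabilities.

    ``token_logits`` is (n_tokens, 4); ``word_index[k]`` gives the word of
    token k (non-decreasing, covering every word). Every word must own at
    least one token and all scores must be finite.
    """
    logits = np.asarray(token_logits, dtype=float)
    if logits.ndim != 2 or logits.shape[1] != N_CLASSES:
        raise ValueError(f"token_logits must be (n_tokens, {N_CLASSES})")
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite token score")
    word_index = np.asarray(word_index, dtype=np.int64)
    if len(word_index) != logits.shape[0]:
        raise ValueError("word_index length != number of token score rows")
    if n_words is None:
        n_words = int(word_index.max()) + 1 if len(word_index) else 0
    counts = np.bincount(word_index, minlength=n_words) \
        if len(word_index) else np.zeros(n_words, dtype=np.int64)
    if np.any(counts == 0):
        missing = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"word {missing} has zero tokens")

    # per-word max over that word's tokens and classes (exact rescaling)
    word_max = np.full(n_words, -np.inf)
    np.maximum.at(word_max, word_index, logits.max(axis=1))
    e = np.exp(logits - word_max[word_index, None])
    num = np.zeros((n_words, N_CLASSES))
    np.add.at(num, word_index, e)
    return num / num.sum(axis=1, keepdims=True)


def assign_word_classes(word_probs: WordProbabilities) -> np.ndarray:
    """Argmax class per word; on ties the first class in (SPE, PRO, PAT, O)
    order wins (numpy argmax returns the first maximum)."""
    word_probs = np.asarray(word_probs)
    return word_probs.argmax(axis=1)


def _collapse_repeats(words: list[str]) -> list[str]:
    """Collapse immediately repeated identical words to one occurrence.

    All-occurrence gold labeling duplicates a keyword when the phrase
    appears twice; only adjacent duplicates are collapsed so legitimate
    repetition inside distinct phrases survives.
    """
    out: list[str] = []
    for w in words:
        if not out or out[-1] != w:
            out.append(w)
    return out


def assemble_keywords(
    words: Sequence[str],
    word_classes: Sequence[int],
    statement_id: str = "",
) -> ExtractionResult:
    """Join, per keyword type, the words of that class in text order."""
    if len(words) != len(word_classes):
        raise ValueError("words and word_classes lengths differ")
    strings = {}
    for type_name, cls in (("specimen", "SPE"), ("procedure", "PRO"),
                           ("pathology", "PAT")):
        idx = CLASS_TO_INDEX[cls]
        selected = [w for w, c in zip(words, word_classes) if c == idx]
        strings[type_name] = " ".join(_collapse_repeats(selected))
    return ExtractionResult(
        statement_id=statement_id,
        specimen=strings["specimen"],
        procedure=strings["procedure"],
        pathology=strings["pathology"],
        word_classes=tuple(int(c) for c in word_classes))


def extract_statement(model, statement: TokenizedStatement,
                      ) -> ExtractionResult:
    """Full decode for one statement: predict, aggregate, argmax, assemble."""
    logits = model.predict_logits(statement.tokens)
    if statement.n_words == 0:
        return ExtractionResult(statement.statement_id, "", "", "", ())
    probs = aggregate_word_probs(logits, statement.word_index,
                                 statement.n_words)
    classes = assign_word_classes(probs)
    return assemble_keywords(statement.words, classes,
                             statement.statement_id)
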