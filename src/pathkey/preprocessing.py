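"""Report preprocessing: splitting, normalization, subword tokenization,
and gold-label alignment.

The normalization contract is deliberately strict: case-fold, then treat
every character outside ``[a-z0-9]`` as a word boundary. Digits are kept
because report keywords may contain them (stage codes such as ``t2n0m0``).

Subword segmentation is greedy longest-match-first over a WordPiece-style
vocabulary (continuation pieces carry the ``##`` prefix). When no
segmentation of a word exists, the unknown token is emitted for the whole
word. A small frequency-based trainer builds a vocabulary from a corpus when
no external vocabulary file is supplied.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from .classes import CLASS_TO_INDEX, O_INDEX
from .errors import AlignmentError, ConfigurationError
from .synthetic import GoldAnnotation

__all__ = [
    "Statement",
    "TokenizedStatement",
    "SubwordVocabulary",
    "split_statements",
    "normalize",
    "tokenize_word",
    "tokenize_statement",
    "detokenize_word",
    "align_labels",
    "train_wordpiece_vocabulary",
    "read_conll",
    "write_conll",
    "MAX_TOKENS",
]

logger = logging.getLogger(__name__)

#: Hard cap on tokens per statement (encoder-family sequence limit).
MAX_TOKENS = 512

_NORMALIZE_RE = re.compile(r"[^a-z0-9]+")
_LINEBREAK_SPLIT_RE = re.compile(r"\n{2,}")
CONTINUATION_PREFIX = "##"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Statement:
    """One normalized statement (paragraph) of a report."""

    statement_id: str
    raw_text: str
    words: tuple[str, ...]
    gold: GoldAnnotation | None = None


@dataclass(frozen=True)
class TokenizedStatement:
    """Subword view of a statement with the token -> word alignment.

    ``word_index[k]`` is the position of the word that token ``k`` belongs
    to; it is non-decreasing and covers every word position. When present,
    ``token_tags`` holds one class index per token, and all tokens of one
    word share the word's tag.
    """

    statement_id: str
    tokens: tuple[str, ...]
    word_index: tuple[int, ...]
    words: tuple[str, ...]
    token_tags: tuple[int, ...] | None = None
    gold: GoldAnnotation | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.word_index):
            raise ValueError("tokens and word_index lengths differ")
        if self.token_tags is not None and (
                len(self.token_tags) != len(self.tokens)):
            raise ValueError("token_tags and tokens lengths differ")

    @property
    def n_words(self) -> int:
        return len(self.words)

    def word_tags(self) -> tuple[int, ...]:
        """Per-word tags recovered from per-token tags."""
        if self.token_tags is None:
            raise ValueError("statement has no token tags")
        tags = [O_INDEX] * len(self.words)
        for tok_pos, w in enumerate(self.word_index):
            tags[w] = self.token_tags[tok_pos]
        return tuple(tags)


@dataclass
class SubwordVocabulary:
    """WordPiece-style vocabulary: word-initial and continuation pieces."""

    initial: frozenset[str]
    continuation: frozenset[str]
    unknown_token: str = "[UNK]"

    def __post_init__(self) -> None:
        self.initial = frozenset(self.initial) | {self.unknown_token}
        self.continuation = frozenset(self.continuation)
        # deterministic piece order for model input layers
        self._ordered = tuple(
            sorted(self.initial)
            + sorted(CONTINUATION_PREFIX + p for p in self.continuation))

    @property
    def entries(self) -> tuple[str, ...]:
        """All pieces in file dialect (continuations ``##``-prefixed)."""
        return self._ordered

    def __len__(self) -> int:
        return len(self._ordered)

    @classmethod
    def from_entries(cls, entries: Iterable[str],
                     unknown_token: str = "[UNK]") -> "SubwordVocabulary":
        initial, continuation = set(), set()
        for e in entries:
            e = e.strip()
            if not e:
                continue
            if e.startswith(CONTINUATION_PREFIX):
                continuation.add(e[len(CONTINUATION_PREFIX):])
            else:
                initial.add(e)
        return cls(initial=frozenset(initial),
                   continuation=frozenset(continuation),
                   unknown_token=unknown_token)

    @classmethod
    def load(cls, path: str | Path,
             unknown_token: str = "[UNK]") -> "SubwordVocabulary":
        """Read the standard one-piece-per-line vocabulary file."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_entries(lines, unknown_token=unknown_token)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.entries) + "\n",
                              encoding="utf-8")


# --------------------------------------------------------------------------
# Splitting and normalization
# --------------------------------------------------------------------------

def split_statements(report_text: str) -> list[str]:
    """Split a report on runs of two or more line breaks.

    Single line breaks stay inside a statement. Empty and whitespace-only
    segments are dropped; order is preserved.
    """
    if report_text is None:
        raise ValueError("report_text is None")
    text = report_text.replace("\r\n", "\n").replace("\r", "\n")
    # collapse blank lines that contain only spaces/tabs into pure breaks
    text = re.sub(r"\n[ \t]+\n", "\n\n", text)
    segments = _LINEBREAK_SPLIT_RE.split(text)
    return [s.strip() for s in segments if s.strip()]


def normalize(raw_text: str) -> list[str]:
    """Lowercase, replace non-alphanumerics with whitespace, split.

    Digits are retained; every character outside ``[a-z0-9]`` acts as a
    word boundary.
    """
    return _NORMALIZE_RE.sub(" ", raw_text.lower()).split()


# --------------------------------------------------------------------------
# WordPiece tokenization
# --------------------------------------------------------------------------

def tokenize_word(word: str, vocab: SubwordVocabulary) -> list[str]:
    """Greedy longest-match-first segmentation of one normalized word.

    The first piece is matched against word-initial entries, subsequent
    pieces against continuation entries (emitted with the ``##`` prefix).
    If the word cannot be fully segmented, ``[unknown_token]`` is returned.
    """
    if not word:
        raise ValueError("cannot tokenize an empty word")
    pieces: list[str] = []
    pos = 0
    n = len(word)
    while pos < n:
        table = vocab.initial if pos == 0 else vocab.continuation
        end = n
        piece = None
        while end > pos:
            cand = word[pos:end]
            if cand in table:
                piece = cand
                break
            end -= 1
        if piece is None:
            return [vocab.unknown_token]
        pieces.append(piece if pos == 0 else CONTINUATION_PREFIX + piece)
        pos = end
    return pieces


def detokenize_word(pieces: Sequence[str]) -> str:
    """Concatenate subword pieces of one word, stripping ``##`` markers."""
    return "".join(
        p[len(CONTINUATION_PREFIX):] if p.startswith(CONTINUATION_PREFIX)
        else p
        for p in pieces)


def tokenize_statement(
    statement: Statement,
    vocab: SubwordVocabulary,
    max_tokens: int = MAX_TOKENS,
    tags: Sequence[int] | None = None,
) -> TokenizedStatement:
    """Tokenize every word of a statement, building the alignment map.

    Statements longer than ``max_tokens`` subwords are hard-truncated with a
    warning. When per-word ``tags`` are given, each token inherits the tag
    of its word.
    """
    tokens: list[str] = []
    word_index: list[int] = []
    token_tags: list[int] | None = [] if tags is not None else None
    kept_words = 0
    truncated = False
    for i, word in enumerate(statement.words):
        pieces = tokenize_word(word, vocab)
        if len(tokens) + len(pieces) > max_tokens:
            truncated = True
            break
        tokens.extend(pieces)
        word_index.extend([i] * len(pieces))
        if token_tags is not None:
            token_tags.extend([int(tags[i])] * len(pieces))
        kept_words += 1
    if truncated:
        logger.warning(
            "statement %s truncated at %d tokens (%d of %d words kept)",
            statement.statement_id, max_tokens, kept_words,
            len(statement.words))
    return TokenizedStatement(
        statement_id=statement.statement_id,
        tokens=tuple(tokens),
        word_index=tuple(word_index),
        words=tuple(statement.words[:kept_words]),
        token_tags=tuple(token_tags) if token_tags is not None else None,
        gold=statement.gold)


# --------------------------------------------------------------------------
# Vocabulary training
# --------------------------------------------------------------------------

def train_wordpiece_vocabulary(
    words: Iterable[str],
    size: int = 2000,
    unknown_token: str = "[UNK]",
) -> SubwordVocabulary:
    """Build a subword vocabulary from a corpus by piece frequency.

    Seeds with every single character observed (in both word-initial and
    continuation form) so any word over the corpus alphabet is tokenizable,
    then spends the remaining budget on whole words by frequency and on
    frequent prefixes/suffixes. This is a simple count-based construction,
    not a likelihood-driven trainer, but it produces the same file dialect
    and greedy segmentation behaviour.
    """
    if size < 1:
        raise ConfigurationError("vocabulary size must be positive")
    word_counts = Counter(words)
    if not word_counts:
        raise ConfigurationError("cannot train a vocabulary on no words")
    chars = sorted({c for w in word_counts for c in w})
    initial: set[str] = set(chars)
    continuation: set[str] = set(chars)
    budget = size - (2 * len(chars) + 1)  # chars in both forms + [UNK]

    # whole words first, most frequent first
    ranked_words = sorted(word_counts.items(),
                          key=lambda kv: (-kv[1], kv[0]))
    word_budget = max(0, int(budget * 0.7))
    for w, _ in ranked_words:
        if word_budget <= 0:
            break
        if len(w) > 1 and w not in initial:
            initial.add(w)
            word_budget -= 1
            budget -= 1

    # frequent prefixes (initial form) and suffixes (continuation form)
    prefix_scores: Counter[str] = Counter()
    suffix_scores: Counter[str] = Counter()
    for w, c in word_counts.items():
        for cut in range(2, len(w)):
            prefix_scores[w[:cut]] += c
            suffix_scores[w[cut:]] += c
    candidates = (
        [("i", p, s) for p, s in prefix_scores.items()]
        + [("c", p, s) for p, s in suffix_scores.items()])
    candidates.sort(key=lambda t: (-t[2], -len(t[1]), t[0], t[1]))
    for kind, piece, _ in candidates:
        if budget <= 0:
            break
        table = initial if kind == "i" else continuation
        if piece not in table:
            table.add(piece)
            budget -= 1
    return SubwordVocabulary(initial=frozenset(initial),
                             continuation=frozenset(continuation),
                             unknown_token=unknown_token)


# --------------------------------------------------------------------------
# Gold-label alignment
# --------------------------------------------------------------------------

def _find_occurrences(words: Sequence[str],
                      phrase: Sequence[str]) -> list[int]:
    """Start positions of every contiguous occurrence of ``phrase``."""
    hits = []
    m = len(phrase)
    if m == 0:
        return hits
    for start in range(len(words) - m + 1):
        if list(words[start:start + m]) == list(phrase):
            hits.append(start)
    return hits


def align_labels(
    words: Sequence[str],
    gold: GoldAnnotation,
    statement_id: str | None = None,
) -> list[int]:
    """Per-word class indices from gold keyword phrases.

    Every occurrence of each gold phrase (contiguous word sequence) is
    tagged with the phrase's class; all remaining words are O. When two
    phrases of different classes claim one word, precedence is
    SPE > PRO > PAT and a warning is logged. A non-empty gold phrase with no
    occurrence raises :class:`AlignmentError`.
    """
    tags = [O_INDEX] * len(words)
    # apply lowest-precedence class first so later classes overwrite
    for attr, cls in (("pathology", "PAT"), ("procedure", "PRO"),
                      ("specimen", "SPE")):
        phrase_text = getattr(gold, attr)
        if not phrase_text:
            continue
        phrase = normalize(phrase_text)
        if not phrase:
            continue
        starts = _find_occurrences(words, phrase)
        if not starts:
            raise AlignmentError(phrase_text, statement_id)
        idx = CLASS_TO_INDEX[cls]
        for s in starts:
            for k in range(s, s + len(phrase)):
                if tags[k] != O_INDEX and tags[k] != idx:
                    logger.warning(
                        "label conflict at word %d (%r) in %s: "
                        "%d overruled by %s", k, words[k],
                        statement_id or "<statement>", tags[k], cls)
                tags[k] = idx
    return tags


# --------------------------------------------------------------------------
# CoNLL-style I/O (token TAB tag, blank line between statements)
# --------------------------------------------------------------------------

def write_conll(statements: Iterable[TokenizedStatement],
                path: str | Path) -> None:
    from .classes import CLASSES
    with Path(path).open("w", encoding="utf-8") as fh:
        for st in statements:
            if st.token_tags is None:
                raise ValueError(
                    f"statement {st.statement_id} has no token tags")
            for tok, tag in zip(st.tokens, st.token_tags):
                fh.write(f"{tok}\t{CLASSES[tag]}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[tuple[list[str], list[int]]]:
    """Read (tokens, tag indices) pairs; alignment maps are not stored in
    the CoNLL dialect, so word boundaries are recovered from ``##``."""
    out: list[tuple[list[str], list[int]]] = []
    tokens: list[str] = []
    tags: list[int] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            if tokens:
                out.append((tokens, tags))
                tokens, tags = [], []
            continue
        tok, tag = line.split("\t")
        tokens.append(tok)
        tags.append(CLASS_TO_INDEX[tag])
    if tokens:
        out.append((tokens, tags))
    return out
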