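"""Wu-Palmer taxonomy similarity between extracted keywords and a standard
medical vocabulary.

The taxonomy is a rooted sense hierarchy (optionally a DAG) with a mapping
from surface words to sense nodes. Depth counts nodes on a shortest path
from the root, with depth(root) = 1, the convention of the dominant WordNet
implementations. For two senses a, b:

    wup(a, b) = 2 * depth(lcs(a, b)) / (depth(a) + depth(b))

where lcs is the deepest common ancestor. Word similarity takes the maximum
over all sense pairs of the two words; a word with no senses scores 0.

A multi-word keyword is compared to a multi-word vocabulary term by
computing the word-pair similarities and averaging the strictly positive
values; a vocabulary term's score for a keyword is that average, and the
keyword's final score is the maximum over all vocabulary terms.
"""

from __future__ import annotations

import csv
from collections import deque
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decoding import ExtractionResult
from .errors import TaxonomyError
from .preprocessing import normalize

__all__ = [
    "Taxonomy", "KeywordSet", "SimilarityScore",
    "wu_palmer", "keyword_term_similarity", "best_vocabulary_match",
    "build_keyword_sets", "similarity_distribution",
    "load_vocabulary_terms",
]


# --------------------------------------------------------------------------
# Taxonomy
# --------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Rooted sense hierarchy with word -> sense mapping.

    ``parents`` maps each node to its parent nodes (multiple parents allowed
    when the hierarchy is a DAG). Exactly one node (the root) has no parent.
    Validation rejects cycles and orphans at load time.
    """

    parents: dict[str, tuple[str, ...]]
    word_senses: dict[str, frozenset[str]]
    _depth: dict[str, int] = field(default_factory=dict, repr=False)
    _ancestors: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        nodes = set(self.parents)
        for node, ps in self.parents.items():
            for p in ps:
                if p not in nodes:
                    raise TaxonomyError(
                        f"parent {p!r} of {node!r} is not a node")
        roots = [n for n, ps in self.parents.items() if not ps]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        # breadth-first shortest-path depths from the root (root depth 1)
        depth = {self.root: 1}
        children: dict[str, list[str]] = {n: [] for n in nodes}
        for n, ps in self.parents.items():
            for p in ps:
                children[p].append(n)
        queue = deque([self.root])
        while queue:
            n = queue.popleft()
            for c in children[n]:
                if c not in depth:
                    depth[c] = depth[n] + 1
                    queue.append(c)
        unreachable = nodes - set(depth)
        if unreachable:
            raise TaxonomyError(
                f"nodes unreachable from root (cycle or orphan): "
                f"{sorted(unreachable)}")
        self._depth = depth
        for word, senses in self.word_senses.items():
            for s in senses:
                if s not in nodes:
                    raise TaxonomyError(
                        f"sense {s!r} of word {word!r} is not a node")

    def depth(self, node: str) -> int:
        return self._depth[node]

    def ancestors(self, node: str) -> frozenset[str]:
        """The node itself plus all its ancestors up to the root."""
        cached = self._ancestors.get(node)
        if cached is not None:
            return cached
        seen = {node}
        queue = deque([node])
        while queue:
            n = queue.popleft()
            for p in self.parents[n]:
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        result = frozenset(seen)
        self._ancestors[node] = result
        return result

    def senses(self, word: str) -> frozenset[str]:
        return self.word_senses.get(word.lower(), frozenset())

    # -- file I/O ----------------------------------------------------------

    @classmethod
    def load(cls, edges_path: str | Path,
             senses_path: str | Path) -> "Taxonomy":
        """Read a TSV edge list (child TAB parent; a child with empty
        parent is the root) and a TSV sense map (word TAB node)."""
        parents: dict[str, list[str]] = {}
        with Path(edges_path).open("r", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or not row[0].strip():
                    continue
                child = row[0].strip()
                parent = row[1].strip() if len(row) > 1 else ""
                parents.setdefault(child, [])
                if parent:
                    parents.setdefault(parent, [])
                    parents[child].append(parent)
        word_senses: dict[str, set[str]] = {}
        with Path(senses_path).open("r", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) < 2 or not row[0].strip():
                    continue
                word_senses.setdefault(
                    row[0].strip().lower(), set()).add(row[1].strip())
        return cls(
            parents={n: tuple(ps) for n, ps in parents.items()},
            word_senses={w: frozenset(s) for w, s in word_senses.items()})


# --------------------------------------------------------------------------
# Similarity primitives
# --------------------------------------------------------------------------

def wu_palmer(taxonomy: Taxonomy, word_a: str, word_b: str) -> float:
    """Max over sense pairs of 2*depth(lcs) / (depth(a) + depth(b)).

    Returns 0 when either word has no senses in the taxonomy.
    """
    senses_a = taxonomy.senses(word_a)
    senses_b = taxonomy.senses(word_b)
    if not senses_a or not senses_b:
        return 0.0
    best = 0.0
    for sa in senses_a:
        anc_a = taxonomy.ancestors(sa)
        da = taxonomy.depth(sa)
        for sb in senses_b:
            common = anc_a & taxonomy.ancestors(sb)
            lcs_depth = max(taxonomy.depth(n) for n in common)
            score = 2.0 * lcs_depth / (da + taxonomy.depth(sb))
            best = max(best, score)
    return best


def keyword_term_similarity(taxonomy: Taxonomy, keyword: str,
                            term: str) -> float:
    """Average of the strictly positive word-pair similarities between a
    keyword and one vocabulary term; 0 when every pair scores 0."""
    kw_words = normalize(keyword)
    term_words = normalize(term)
    if not kw_words or not term_words:
        raise ValueError(
            f"empty keyword or term after normalization: "
            f"{keyword!r} vs {term!r}")
    values = [wu_palmer(taxonomy, kw, tw)
              for kw in kw_words for tw in term_words]
    positive = [v for v in values if v > 0.0]
    return float(np.mean(positive)) if positive else 0.0


@dataclass(frozen=True)
class SimilarityScore:
    keyword: str
    best_term: str
    score: float
    is_zero: bool


def best_vocabulary_match(
    taxonomy: Taxonomy,
    keyword: str,
    vocabulary: Sequence[str],
) -> SimilarityScore:
    """Maximum keyword/term similarity over the vocabulary; the first term
    (file order) achieving the maximum wins ties."""
    if not vocabulary:
        raise ValueError("vocabulary is empty")
    best_score = -1.0
    best_term = vocabulary[0]
    for term in vocabulary:
        s = keyword_term_similarity(taxonomy, keyword, term)
        if s > best_score:
            best_score, best_term = s, term
    return SimilarityScore(keyword=keyword, best_term=best_term,
                           score=best_score, is_zero=best_score == 0.0)


# --------------------------------------------------------------------------
# Keyword sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KeywordSet:
    """Deduplicated keywords of one type (insertion order preserved)."""

    keyword_type: str
    keywords: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.keywords)


def build_keyword_sets(
    results: Iterable[ExtractionResult],
) -> dict[str, KeywordSet]:
    """Unique keyword sets per type, plus the combined specimen+pathology
    set of space-joined "<specimen> <pathology>" composites (statements
    missing either part contribute no composite). Empty strings excluded."""
    results = list(results)
    if not results:
        raise ValueError("no extraction results")
    buckets: dict[str, dict[str, None]] = {
        "specimen": {}, "procedure": {}, "pathology": {},
        "specimen+pathology": {}}
    for res in results:
        for t in ("specimen", "procedure", "pathology"):
            kw = res.keyword(t)
            if kw:
                buckets[t].setdefault(kw)
        if res.specimen and res.pathology:
            buckets["specimen+pathology"].setdefault(
                f"{res.specimen} {res.pathology}")
    return {t: KeywordSet(keyword_type=t, keywords=tuple(d))
            for t, d in buckets.items()}


# --------------------------------------------------------------------------
# Distribution
# --------------------------------------------------------------------------

def similarity_distribution(
    scores: Sequence[SimilarityScore | float],
    n_bins: int = 20,
) -> dict:
    """Fixed-bin histogram of scores on [0, 1] with right-closed bins
    ((k/n, (k+1)/n], first bin closed at 0), plus the zero-score count
    reported separately. Histogram counts sum to the number of scores."""
    if len(scores) == 0:
        raise ValueError("no scores")
    values = np.array([s.score if isinstance(s, SimilarityScore) else
                       float(s) for s in scores])
    if np.any((values < 0) | (values > 1)):
        raise ValueError("scores outside [0, 1]")
    zero_count = int((values == 0.0).sum())
    # right-closed binning: bin k covers (k/n, (k+1)/n]; zeros land in bin 0
    idx = np.ceil(values * n_bins).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return {"bin_edges": edges.tolist(),
            "counts": counts.tolist(),
            "zero_count": zero_count,
            "n_scores": int(len(values))}


def load_vocabulary_terms(path: str | Path) -> list[str]:
    """One vocabulary term per line, UTF-8; blank lines skipped."""
    return [ln.strip()
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip()]
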