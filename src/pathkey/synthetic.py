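"""Synthetic pathology-report corpus generator.

Real pathology reports are privacy-restricted, so every downstream stage of
the pipeline is exercised on generated corpora that reproduce the structural
features of hospital reports:

* one report holds 1..k *statements* (one per specimen part), separated by
  runs of two or more line breaks;
* an optional free-text note block, also set off by blank lines, trails the
  report and carries no keywords;
* each statement embeds exactly one specimen phrase, one procedure phrase
  and one pathology phrase among filler words — keywords occur in the text
  but are not necessarily adjacent;
* occasional typos corrupt filler words (keyword words are left intact so
  gold labels stay well defined).

All statements of one report describe parts of the same case: they share the
specimen and procedure phrase, and multi-part reports carry "Part k."
prefixes. This mirrors multi-part reports for a single excision and makes
report membership statistically identifiable, so that next-statement
pre-training on the generated corpus is a learnable task by construction.

The three keyword lexicons are pairwise word-disjoint (and disjoint from the
filler lexicon), which makes the word -> class mapping unambiguous: a
"separable" corpus on which a perfect tagger can recover every gold keyword.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "CorpusConfig",
    "GoldAnnotation",
    "GeneratedStatement",
    "Report",
    "generate_corpus",
    "inject_typos",
    "iter_statements",
    "train_test_split",
    "write_jsonl",
    "read_jsonl",
    "DEFAULT_SPECIMEN_LEXICON",
    "DEFAULT_PROCEDURE_LEXICON",
    "DEFAULT_PATHOLOGY_LEXICON",
    "DEFAULT_FILLER_LEXICON",
]


# --------------------------------------------------------------------------
# Default lexicons. Sizes 50/20/60 echo the study dataset's unique-keyword
# ratio, where procedure has far fewer distinct values than the other types.
# Words are unique to one class so the generated corpora are separable.
# --------------------------------------------------------------------------

DEFAULT_SPECIMEN_LEXICON: tuple[str, ...] = (
    "stomach", "gastric antrum", "gastric body", "duodenum", "esophagus",
    "ascending colon", "transverse colon", "descending colon",
    "sigmoid colon", "rectum", "cecum", "terminal ileum", "appendix",
    "liver", "gallbladder", "pancreas", "left breast", "right breast",
    "thyroid", "prostate", "urinary bladder", "left kidney", "right kidney",
    "uterine cervix", "endometrium", "ovary", "fallopian tube", "vagina",
    "scalp skin", "back skin", "tonsil", "nasal cavity", "larynx", "lung",
    "bronchus", "pleura", "mediastinal lymph node", "axillary lymph node",
    "cervical lymph node", "inguinal lymph node", "bone marrow", "spleen",
    "adrenal", "ureter", "urethra", "testis", "epididymis", "parotid",
    "tongue", "soft palate",
)

DEFAULT_PROCEDURE_LEXICON: tuple[str, ...] = (
    "biopsy", "punch biopsy", "needle biopsy", "core needle biopsy",
    "endoscopic biopsy", "colonoscopic biopsy", "incisional biopsy",
    "excision", "wide excision", "polypectomy", "curettage", "hysterectomy",
    "mastectomy", "lumpectomy", "gastrectomy", "colectomy",
    "cholecystectomy", "appendectomy", "thyroidectomy",
    "fine needle aspiration",
)

DEFAULT_PATHOLOGY_LEXICON: tuple[str, ...] = (
    "chronic gastritis", "acute gastritis", "chronic active gastritis",
    "intestinal metaplasia", "tubular adenoma", "villous adenoma",
    "tubulovillous adenoma", "hyperplastic polyp", "inflammatory polyp",
    "adenocarcinoma", "mucinous adenocarcinoma", "papillary adenocarcinoma",
    "signet ring cell carcinoma", "squamous cell carcinoma",
    "basal cell carcinoma", "invasive ductal carcinoma",
    "invasive lobular carcinoma", "intraductal carcinoma",
    "papillary carcinoma", "follicular carcinoma", "medullary carcinoma",
    "hepatocellular carcinoma", "cholangiocarcinoma", "renal cell carcinoma",
    "urothelial carcinoma", "neuroendocrine tumor",
    "gastrointestinal stromal tumor", "leiomyoma", "leiomyosarcoma",
    "lipoma", "liposarcoma", "fibroadenoma", "fibrosis", "steatosis",
    "cirrhosis", "chronic hepatitis", "acute appendicitis",
    "chronic cholecystitis", "cholesterolosis", "diverticulosis",
    "diverticulitis", "ulcerative colitis", "nodular hyperplasia",
    "atypical hyperplasia", "squamous metaplasia", "low grade dysplasia",
    "high grade dysplasia", "carcinoid tumor", "lymphoma",
    "hodgkin lymphoma", "plasmacytoma", "melanoma", "nevus",
    "seborrheic keratosis", "actinic keratosis", "epidermal cyst",
    "granuloma", "tuberculosis", "endometriosis", "teratoma",
)

DEFAULT_FILLER_LEXICON: tuple[str, ...] = (
    "the", "a", "an", "is", "are", "was", "and", "or", "of", "with",
    "without", "for", "from", "at", "on", "this", "that", "these",
    "received", "labeled", "measuring", "approximately", "size", "cm", "mm",
    "fragments", "fragment", "tissue", "sections", "section", "microscopic",
    "examination", "reveals", "shows", "showing", "seen", "noted",
    "present", "identified", "evidence", "no", "not", "consistent",
    "compatible", "suggestive", "involving", "surface", "focal", "mild",
    "moderate", "severe", "scattered", "multiple", "single", "small",
    "large", "otherwise", "unremarkable", "within", "limits", "normal",
    "comment", "clinical", "correlation", "recommended", "material",
    "submitted", "representative", "margin", "margins", "free",
    "1", "2", "3", "4", "5", "10", "0", "t2n0m0", "3x2",
)

_WORD_RE = re.compile(r"[A-Za-z0-9]+")


def _phrase_words(phrases: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for p in phrases:
        out.update(w.lower() for w in _WORD_RE.findall(p))
    return out


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldAnnotation:
    """Exact keyword strings for one statement.

    Phrases are empty strings for statements without keywords (trailing note
    blocks), so that every split segment of a report carries a gold record.
    """

    specimen: str = ""
    procedure: str = ""
    pathology: str = ""

    def as_dict(self) -> dict[str, str]:
        return dataclasses.asdict(self)

    @property
    def is_empty(self) -> bool:
        return not (self.specimen or self.procedure or self.pathology)


@dataclass(frozen=True)
class GeneratedStatement:
    text: str
    gold: GoldAnnotation


@dataclass(frozen=True)
class Report:
    report_id: str
    text: str
    statements: tuple[GeneratedStatement, ...]


@dataclass
class CorpusConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_reports: int = 500
    specimen_lexicon: Sequence[str] = DEFAULT_SPECIMEN_LEXICON
    procedure_lexicon: Sequence[str] = DEFAULT_PROCEDURE_LEXICON
    pathology_lexicon: Sequence[str] = DEFAULT_PATHOLOGY_LEXICON
    filler_lexicon: Sequence[str] = DEFAULT_FILLER_LEXICON
    max_specimens_per_report: int = 3
    note_probability: float = 0.3
    typo_rate: float = 0.05
    typo_keywords: bool = False  # allow typos inside keyword words
    part_labels: bool = True     # "Part k." prefixes on multi-part reports
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be a positive count")
        if self.max_specimens_per_report < 1:
            raise ConfigurationError(
                "max_specimens_per_report must be a positive count")
        for name in ("specimen_lexicon", "procedure_lexicon",
                     "pathology_lexicon", "filler_lexicon"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} is empty")
        for name in ("note_probability", "typo_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        spe = _phrase_words(self.specimen_lexicon)
        pro = _phrase_words(self.procedure_lexicon)
        pat = _phrase_words(self.pathology_lexicon)
        fil = _phrase_words(self.filler_lexicon)
        pairs = [("specimen", spe, "procedure", pro),
                 ("specimen", spe, "pathology", pat),
                 ("procedure", pro, "pathology", pat)]
        for na, a, nb, b in pairs:
            common = a & b
            if common:
                raise ConfigurationError(
                    f"{na} and {nb} lexicons share words: {sorted(common)}")
        common = fil & (spe | pro | pat)
        if common:
            raise ConfigurationError(
                f"filler lexicon shares words with keyword lexicons: "
                f"{sorted(common)}")

    @property
    def keyword_words(self) -> frozenset[str]:
        """All words that belong to some keyword phrase (never typo'd)."""
        return frozenset(
            _phrase_words(self.specimen_lexicon)
            | _phrase_words(self.procedure_lexicon)
            | _phrase_words(self.pathology_lexicon))


# --------------------------------------------------------------------------
# Typo injection
# --------------------------------------------------------------------------

_ALPHA = "abcdefghijklmnopqrstuvwxyz"


def _perturb_word(word: str, rng: np.random.Generator) -> str:
    """One character substitution or deletion; always changes the word."""
    pos = int(rng.integers(len(word)))
    if len(word) > 1 and rng.random() < 0.5:
        return word[:pos] + word[pos + 1:]
    old = word[pos].lower()
    choices = [c for c in _ALPHA if c != old]
    new = choices[int(rng.integers(len(choices)))]
    return word[:pos] + new + word[pos + 1:]


def inject_typos(
    statement_text: str,
    typo_rate: float,
    seed: int | np.random.Generator,
    protected_words: frozenset[str] | set[str] = frozenset(),
) -> str:
    """Corrupt words of a statement with probability ``typo_rate`` each.

    Words whose lowercased form is in ``protected_words`` (the keyword
    words) are never touched, so gold annotations stay recoverable. Each
    corrupted word receives exactly one character substitution or deletion.
    Deterministic for a fixed seed.
    """
    if not 0.0 <= typo_rate <= 1.0:
        raise ConfigurationError(f"typo_rate={typo_rate} outside [0, 1]")
    if typo_rate == 0.0:
        return statement_text
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def _sub(m: re.Match[str]) -> str:
        word = m.group(0)
        if word.lower() in protected_words:
            return word
        if rng.random() >= typo_rate:
            return word
        for _ in range(10):  # avoid colliding with a protected word
            cand = _perturb_word(word, rng)
            if cand.lower() not in protected_words:
                return cand
        return word

    return _WORD_RE.sub(_sub, statement_text)


# --------------------------------------------------------------------------
# Statement templates
# --------------------------------------------------------------------------
# Each template is a format string over {S}pecimen, {P}rocedure,
# {D}iagnosis and numbered filler slots; the headed, colon-delimited style
# follows the layout of institutional reports. Filler slots keep the three
# keyword phrases from always being adjacent.

_TEMPLATES: tuple[str, ...] = (
    "{S}, {P}:\n  - {D} {F0} {F1}.",
    "{S}, {P}:\n  {F0} {F1} {D}, {F2} {F3} {F4}.",
    "{S}, {P}:\n  {F0} {F1} {F2} {D}.",
    "{P}; {S}:\n  - {D} {F0} {F1} {F2} {F3}.",
    "{S}, {P}:\n  {F0} {D} {F1} {F2}. {F3} {F4} {F5}.",
)

_MAX_FILLER_SLOTS = 6


def _fill_template(template: str, spe: str, pro: str, pat: str,
                   fillers: Sequence[str]) -> str:
    mapping = {"S": spe.capitalize(), "P": pro, "D": pat}
    for k in range(_MAX_FILLER_SLOTS):
        mapping[f"F{k}"] = fillers[k] if k < len(fillers) else ""
    text = template.format_map(mapping)
    return re.sub(r" +", " ", text)


def _note_block(rng: np.random.Generator, fillers: Sequence[str]) -> str:
    n = int(rng.integers(6, 13))
    idx = rng.integers(0, len(fillers), size=n)
    words = [fillers[int(i)] for i in idx]
    return "Note) " + " ".join(words) + "."


# --------------------------------------------------------------------------
# Corpus generation
# --------------------------------------------------------------------------

def generate_corpus(config: CorpusConfig) -> list[Report]:
    """Generate ``config.n_reports`` reports with gold keyword annotations.

    Identical configs (including the seed) produce byte-identical corpora.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    spe_lex = list(config.specimen_lexicon)
    pro_lex = list(config.procedure_lexicon)
    pat_lex = list(config.pathology_lexicon)
    fil_lex = list(config.filler_lexicon)
    protected = config.keyword_words

    reports: list[Report] = []
    for r in range(config.n_reports):
        n_parts = int(rng.integers(1, config.max_specimens_per_report + 1))
        # one case per report: specimen and procedure shared across parts
        spe = spe_lex[int(rng.integers(len(spe_lex)))]
        pro = pro_lex[int(rng.integers(len(pro_lex)))]
        statements: list[GeneratedStatement] = []
        for k in range(n_parts):
            pat = pat_lex[int(rng.integers(len(pat_lex)))]
            template = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
            n_fill = int(rng.integers(3, _MAX_FILLER_SLOTS + 1))
            fillers = [fil_lex[int(i)]
                       for i in rng.integers(0, len(fil_lex), size=n_fill)]
            text = _fill_template(template, spe, pro, pat, fillers)
            if n_parts > 1 and config.part_labels:
                text = f"Part {k + 1}. {text}"
            if config.typo_rate > 0:
                guard = frozenset() if config.typo_keywords else protected
                text = inject_typos(text, config.typo_rate, rng, guard)
            statements.append(GeneratedStatement(
                text=text,
                gold=GoldAnnotation(specimen=spe, procedure=pro,
                                    pathology=pat)))
        if rng.random() < config.note_probability:
            note = _note_block(rng, fil_lex)
            if config.typo_rate > 0:
                note = inject_typos(note, config.typo_rate, rng, protected)
            statements.append(GeneratedStatement(
                text=note, gold=GoldAnnotation()))
        seps = ["\n\n" if rng.random() < 0.7 else "\n\n\n"
                for _ in range(len(statements) - 1)]
        parts = [statements[0].text]
        for sep, st in zip(seps, statements[1:]):
            parts.append(sep)
            parts.append(st.text)
        reports.append(Report(
            report_id=f"R{r:05d}",
            text="".join(parts),
            statements=tuple(statements)))
    return reports


def iter_statements(
    reports: Iterable[Report],
) -> list[tuple[str, str, GoldAnnotation]]:
    """Flatten reports into (statement_id, text, gold) triples."""
    out = []
    for rep in reports:
        for i, st in enumerate(rep.statements):
            out.append((f"{rep.report_id}:{i}", st.text, st.gold))
    return out


def train_test_split(
    items: Sequence,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list, list]:
    """Random statement-level split (default 90/10) with a fixed seed."""
    if not 0.0 <= test_fraction <= 1.0:
        raise ConfigurationError(
            f"test_fraction={test_fraction} outside [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_test = int(round(test_fraction * len(items)))
    test_idx = set(order[:n_test].tolist())
    train = [items[i] for i in range(len(items)) if i not in test_idx]
    test = [items[i] for i in range(len(items)) if i in test_idx]
    return train, test


# --------------------------------------------------------------------------
# JSONL I/O
# --------------------------------------------------------------------------

def write_jsonl(reports: Iterable[Report], path: str | Path) -> None:
    """One record per report: {report_id, text, statements: [...]}."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rep in reports:
            rec = {
                "report_id": rep.report_id,
                "text": rep.text,
                "statements": [
                    {"text": st.text, **st.gold.as_dict()}
                    for st in rep.statements
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[Report]:
    reports = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            statements = tuple(
                GeneratedStatement(
                    text=s["text"],
                    gold=GoldAnnotation(
                        specimen=s.get("specimen", ""),
                        procedure=s.get("procedure", ""),
                        pathology=s.get("pathology", "")))
                for s in rec.get("statements", []))
            reports.append(Report(
                report_id=rec["report_id"],
                text=rec["text"],
                statements=statements))
    return reports
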