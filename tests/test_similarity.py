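"""Wu-Palmer similarity on a hand-built fixture taxonomy, keyword sets,
and the score distribution.

Fixture depths (root "entity" = 1): anatomy/disease/intervention = 2;
organ/tissue, neoplasm/inflammation, biopsy/excision = 3; digestive/gland,
benign/malignant, gastritis/colitis = 4; stomach/colon/adenoma/carcinoma
etc. = 5; sigmoid/rectum/tubular/villous/adenocarcinoma = 6.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathkey.decoding import ExtractionResult
from pathkey.errors import TaxonomyError
from pathkey.similarity import (KeywordSet, SimilarityScore, Taxonomy,
                                best_vocabulary_match, build_keyword_sets,
                                keyword_term_similarity,
                                similarity_distribution, wu_palmer)

WORDS = ["stomach", "colon", "liver", "sigmoid", "rectum", "thyroid",
         "prostate", "adenoma", "tubular", "villous", "carcinoma",
         "adenocarcinoma", "lipoma", "gastritis", "colitis", "biopsy",
         "excision", "polyp", "epithelium", "mucosa"]


class TestWuPalmer:
    def test_identical_single_sense_word_is_one(self, fixture_taxonomy):
        for w in ("stomach", "adenoma", "biopsy"):
            assert wu_palmer(fixture_taxonomy, w, w) == 1.0

    def test_worked_sibling_case_two_thirds(self, fixture_taxonomy):
        # sigmoid (6) and rectum (6) share lcs colon (5): 2*5/12 = 5/6;
        # stomach (5) and colon (5) share lcs digestive (4): 2*4/10 = 4/5;
        # the textbook depth-3 worked case: tubular (6) vs villous (6),
        # lcs adenoma (5) -> 2*5/12; use gastritis (4) vs colitis (4),
        # lcs inflammation (3) -> 2*3/8 = 3/4.
        assert wu_palmer(fixture_taxonomy, "sigmoid", "rectum") == \
            pytest.approx(5 / 6, abs=1e-12)
        assert wu_palmer(fixture_taxonomy, "stomach", "colon") == \
            pytest.approx(4 / 5, abs=1e-12)
        assert wu_palmer(fixture_taxonomy, "gastritis", "colitis") == \
            pytest.approx(3 / 4, abs=1e-12)

    def test_depth_two_sibling_case(self):
        # minimal fixture: root -> A -> {B, C}; both at depth 3, lcs A at
        # depth 2 -> 2*2/(3+3) = 2/3
        tax = Taxonomy(
            parents={"root": (), "a": ("root",), "b": ("a",),
                     "c": ("a",)},
            word_senses={"b": frozenset({"b"}), "c": frozenset({"c"})})
        assert wu_palmer(tax, "b", "c") == pytest.approx(2 / 3, abs=1e-12)

    def test_cross_branch_distant_pair(self, fixture_taxonomy):
        # stomach (5) vs carcinoma (5): lcs entity (1) -> 2*1/10 = 1/5
        assert wu_palmer(fixture_taxonomy, "stomach", "carcinoma") == \
            pytest.approx(1 / 5, abs=1e-12)

    def test_ancestor_descendant(self, fixture_taxonomy):
        # adenoma (5) vs tubular (6): lcs adenoma -> 2*5/11
        assert wu_palmer(fixture_taxonomy, "adenoma", "tubular") == \
            pytest.approx(10 / 11, abs=1e-12)

    def test_uncovered_word_scores_zero(self, fixture_taxonomy):
        assert wu_palmer(fixture_taxonomy, "stomach", "zzz") == 0.0
        assert wu_palmer(fixture_taxonomy, "zzz", "qqq") == 0.0

    def test_multi_sense_takes_best_pair(self, fixture_taxonomy):
        # polyp has senses {benign(4), mucosa(4)}; against adenoma(5) the
        # benign sense wins: lcs benign -> 2*4/9; mucosa sense would give
        # lcs anatomy(2) -> 4/9 only.
        assert wu_palmer(fixture_taxonomy, "polyp", "adenoma") == \
            pytest.approx(8 / 9, abs=1e-12)

    @settings(max_examples=150, deadline=None)
    @given(a=st.sampled_from(WORDS), b=st.sampled_from(WORDS))
    def test_symmetric_and_bounded(self, fixture_taxonomy, a, b):
        s = wu_palmer(fixture_taxonomy, a, b)
        assert 0.0 <= s <= 1.0
        assert s == wu_palmer(fixture_taxonomy, b, a)

    def test_root_depth_convention(self, fixture_taxonomy):
        assert fixture_taxonomy.depth("entity") == 1
        assert fixture_taxonomy.depth("sigmoid") == 6


class TestTaxonomyValidation:
    def test_cycle_rejected(self):
        with pytest.raises(TaxonomyError):
            Taxonomy(parents={"r": (), "a": ("b",), "b": ("a",)},
                     word_senses={})

    def test_two_roots_rejected(self):
        with pytest.raises(TaxonomyError, match="root"):
            Taxonomy(parents={"r1": (), "r2": ()}, word_senses={})

    def test_unknown_sense_rejected(self):
        with pytest.raises(TaxonomyError):
            Taxonomy(parents={"r": ()},
                     word_senses={"w": frozenset({"nope"})})

    def test_dag_multiple_parents_uses_shortest_depth(self):
        tax = Taxonomy(
            parents={"r": (), "a": ("r",), "b": ("a",), "c": ("r", "b")},
            word_senses={"c": frozenset({"c"})})
        assert tax.depth("c") == 2  # via the direct root link

    def test_file_round_trip(self, tmp_path, fixture_taxonomy):
        edges = tmp_path / "tax.tsv"
        lines = []
        for child, parents in fixture_taxonomy.parents.items():
            if not parents:
                lines.append(f"{child}\t")
            for p in parents:
                lines.append(f"{child}\t{p}")
        edges.write_text("\n".join(lines) + "\n", encoding="utf-8")
        senses = tmp_path / "senses.tsv"
        senses.write_text(
            "\n".join(f"{w}\t{s}"
                      for w, ss in fixture_taxonomy.word_senses.items()
                      for s in sorted(ss)) + "\n", encoding="utf-8")
        back = Taxonomy.load(edges, senses)
        for a in ("stomach", "tubular", "polyp"):
            for b in ("colon", "adenoma"):
                assert wu_palmer(back, a, b) == \
                    wu_palmer(fixture_taxonomy, a, b)


class TestKeywordTermSimilarity:
    def test_single_word_pair_equals_wu_palmer(self, fixture_taxonomy):
        assert keyword_term_similarity(
            fixture_taxonomy, "stomach", "colon") == \
            wu_palmer(fixture_taxonomy, "stomach", "colon")

    def test_zero_pairs_excluded_from_mean(self, fixture_taxonomy):
        # "zzz" contributes only zeros; the mean is over the non-zero
        # stomach/colon pair alone
        expected = wu_palmer(fixture_taxonomy, "stomach", "colon")
        assert keyword_term_similarity(
            fixture_taxonomy, "stomach zzz", "colon") == \
            pytest.approx(expected, abs=1e-12)

    def test_hand_averaged_two_word_case(self, fixture_taxonomy):
        # pairs: (sigmoid,colon)=2*5/11, (adenoma,colon)=2*3/10 via
        # lcs entity? adenoma(5) vs colon(5): lcs entity(1) -> 1/5.
        expected = np.mean([
            wu_palmer(fixture_taxonomy, "sigmoid", "colon"),
            wu_palmer(fixture_taxonomy, "adenoma", "colon")])
        got = keyword_term_similarity(fixture_taxonomy,
                                      "sigmoid adenoma", "colon")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_coverage_returns_zero(self, fixture_taxonomy):
        assert keyword_term_similarity(fixture_taxonomy, "zzz", "qqq") \
            == 0.0

    def test_empty_after_normalization_rejected(self, fixture_taxonomy):
        with pytest.raises(ValueError):
            keyword_term_similarity(fixture_taxonomy, "***", "colon")

    def test_removing_zero_pair_never_decreases(self, fixture_taxonomy):
        with_zero = keyword_term_similarity(
            fixture_taxonomy, "stomach zzz", "colon gastritis")
        without = keyword_term_similarity(
            fixture_taxonomy, "stomach", "colon gastritis")
        assert with_zero == pytest.approx(without, abs=1e-12)


class TestBestVocabularyMatch:
    def test_self_similarity_is_one(self, fixture_taxonomy):
        score = best_vocabulary_match(
            fixture_taxonomy, "gastritis",
            ["stomach", "gastritis", "adenoma"])
        assert score.score == pytest.approx(1.0, abs=1e-12)
        assert score.best_term == "gastritis"
        assert not score.is_zero

    def test_multiword_self_match_includes_cross_pairs(self,
                                                       fixture_taxonomy):
        """All-pairs averaging keeps cross pairs, so a multi-word phrase
        matched against itself scores the mean of all four word pairs
        (here (2 + 2*10/11) / 4), not 1."""
        score = keyword_term_similarity(fixture_taxonomy, "sigmoid colon",
                                        "sigmoid colon")
        expected = (2 * 1.0
                    + 2 * wu_palmer(fixture_taxonomy, "sigmoid",
                                    "colon")) / 4
        assert score == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_two_term_case(self, fixture_taxonomy):
        vocab = ["carcinoma", "rectum"]
        s1 = keyword_term_similarity(fixture_taxonomy, "sigmoid",
                                     "carcinoma")
        s2 = keyword_term_similarity(fixture_taxonomy, "sigmoid",
                                     "rectum")
        best = best_vocabulary_match(fixture_taxonomy, "sigmoid", vocab)
        assert best.score == max(s1, s2)
        assert best.best_term == ("carcinoma" if s1 >= s2 else "rectum")

    def test_ties_take_first_in_file_order(self, fixture_taxonomy):
        best = best_vocabulary_match(fixture_taxonomy, "tubular",
                                     ["sigmoid colon", "colon sigmoid"])
        assert best.best_term == "sigmoid colon"

    def test_uncovered_keyword_flags_zero(self, fixture_taxonomy):
        best = best_vocabulary_match(fixture_taxonomy, "zzz",
                                     ["colon", "stomach"])
        assert best.is_zero
        assert best.score == 0.0

    def test_monotone_in_vocabulary_size(self, fixture_taxonomy, rng):
        vocab = ["gastritis", "lipoma", "rectum", "carcinoma", "colon"]
        prev = -1.0
        for k in range(1, len(vocab) + 1):
            s = best_vocabulary_match(fixture_taxonomy, "sigmoid adenoma",
                                      vocab[:k]).score
            assert s >= prev
            prev = s

    def test_empty_vocabulary_rejected(self, fixture_taxonomy):
        with pytest.raises(ValueError):
            best_vocabulary_match(fixture_taxonomy, "colon", [])


def _res(sid, spe="", pro="", pat=""):
    return ExtractionResult(statement_id=sid, specimen=spe, procedure=pro,
                            pathology=pat, word_classes=())


class TestBuildKeywordSets:
    def test_per_type_dedup(self):
        sets = build_keyword_sets(
            [_res(f"s{i}", spe="stomach") for i in range(3)])
        assert sets["specimen"].keywords == ("stomach",)
        assert len(sets["procedure"]) == 0

    def test_combined_pair_then_dedup(self):
        results = [_res("a", spe="colon", pat="adenoma"),
                   _res("b", spe="colon", pat="adenoma"),
                   _res("c", spe="colon", pat="carcinoma")]
        sets = build_keyword_sets(results)
        assert sets["specimen+pathology"].keywords == \
            ("colon adenoma", "colon carcinoma")

    def test_missing_part_contributes_no_composite(self):
        sets = build_keyword_sets([_res("a", spe="colon", pat="")])
        assert len(sets["specimen+pathology"]) == 0
        assert sets["specimen"].keywords == ("colon",)

    def test_idempotent_dedup(self):
        results = [_res("a", spe="colon", pro="biopsy", pat="adenoma")] * 4
        once = build_keyword_sets(results)
        again = build_keyword_sets(results + results)
        assert {t: s.keywords for t, s in once.items()} == \
            {t: s.keywords for t, s in again.items()}


class TestSimilarityDistribution:
    def test_all_ones_in_top_bin(self):
        hist = similarity_distribution([1.0] * 5)
        assert hist["counts"][-1] == 5
        assert sum(hist["counts"]) == 5
        assert hist["zero_count"] == 0

    def test_zero_counted_separately_and_in_first_bin(self):
        hist = similarity_distribution([0.0, 0.5, 1.0])
        assert hist["zero_count"] == 1
        assert sum(hist["counts"]) == 3
        assert hist["counts"][0] == 1

    def test_right_closed_edges(self):
        hist = similarity_distribution([0.05, 0.050001], n_bins=20)
        # 0.05 lies in the first bin (0, 0.05]; the next value in (0.05,..]
        assert hist["counts"][0] == 1
        assert hist["counts"][1] == 1

    def test_conservation_on_random_scores(self, rng):
        scores = rng.uniform(0, 1, 500)
        hist = similarity_distribution(list(scores))
        assert sum(hist["counts"]) == 500

    def test_scores_objects_accepted(self):
        scores = [SimilarityScore("k", "t", 0.7, False),
                  SimilarityScore("k2", "t", 0.0, True)]
        hist = similarity_distribution(scores)
        assert hist["zero_count"] == 1
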