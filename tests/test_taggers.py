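"""Bayes baseline, neural taggers (with finite-difference gradient checks),
and next-statement-prediction pre-training."""

import math

import numpy as np
import pytest

from pathkey.classes import CLASS_TO_INDEX, N_CLASSES
from pathkey.errors import CapabilityError, ConfigurationError
from pathkey.networks import (ConvTagger, RecurrentTagger,
                              TransformerTagger, masked_cross_entropy,
                              softmax)
from pathkey.preprocessing import TokenizedStatement
from pathkey.taggers import (BayesModel, NSPPair, TrainConfig, load_model,
                             make_nsp_corpus, predict, pretrain_nsp,
                             save_model, train_bayes, train_neural)

SPE, PRO, PAT, O = (CLASS_TO_INDEX[c] for c in ("SPE", "PRO", "PAT", "O"))


def make_statement(tokens, tags, sid="s"):
    n = len(tokens)
    return TokenizedStatement(
        statement_id=sid, tokens=tuple(tokens),
        word_index=tuple(range(n)), words=tuple(tokens),
        token_tags=tuple(tags))


class TestBayes:
    def test_dominant_count_wins(self):
        stmts = [make_statement(["biopsy"], [PRO], f"s{i}")
                 for i in range(10)]
        model = train_bayes(stmts)
        assert predict(model, stmts[0]).argmax() == PRO

    def test_unseen_token_follows_prior(self):
        # O dominates the training distribution
        stmts = [make_statement(["a", "b", "c", "biopsy"],
                                [O, O, O, PRO], "s")]
        model = train_bayes(stmts)
        scores = model.predict_logits(["neverseen"])
        assert scores[0].argmax() == O

    def test_hand_computed_smoothed_log_odds(self):
        """Counts ('a',SPE)=3, ('a',O)=1, alpha=1: verify scores against
        independently hand-evaluated Laplace-smoothed formula."""
        stmts = [make_statement(["a"], [SPE], f"p{i}") for i in range(3)]
        stmts.append(make_statement(["a"], [O], "q"))
        model = train_bayes(stmts, smoothing=1.0)
        scores = model.predict_logits(["a"])[0]
        V = 1  # one distinct token
        total = 4
        for c, count_tc, count_c in ((SPE, 3, 3), (O, 1, 1)):
            expected = (math.log((count_tc + 1) / (count_c + V))
                        + math.log((count_c + 1) / (total + 4)))
            assert scores[c] == pytest.approx(expected, abs=1e-12)
        assert scores[SPE] > scores[O]

    def test_scores_softmax_to_distribution(self, tokenized):
        model = train_bayes(tokenized[:100])
        for st in tokenized[:20]:
            if not st.tokens:
                continue
            p = softmax(predict(model, st))
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_is_pure(self, tokenized):
        model = train_bayes(tokenized[:50])
        st = tokenized[0]
        assert np.array_equal(predict(model, st), predict(model, st))

    def test_empty_statement_empty_logits(self, tokenized):
        model = train_bayes(tokenized[:10])
        assert model.predict_logits([]).shape == (0, N_CLASSES)

    def test_unique_class_corpus_perfect_training_accuracy(self):
        vocab_classes = {"w%d" % i: i % 4 for i in range(40)}
        stmts = [make_statement([w], [c], w)
                 for w, c in vocab_classes.items()]
        model = train_bayes(stmts)
        for w, c in vocab_classes.items():
            assert model.predict_logits([w])[0].argmax() == c

    def test_no_keyword_tags_warns(self):
        with pytest.warns(UserWarning, match="no keyword"):
            train_bayes([make_statement(["a"], [O], "s")])

    def test_counts_tsv_round_trip(self, tmp_path, tokenized):
        model = train_bayes(tokenized[:50])
        model.save_counts(tmp_path / "counts.tsv")
        back = BayesModel.load_counts(tmp_path / "counts.tsv")
        st = tokenized[3]
        assert np.allclose(predict(model, st), predict(back, st))


# ---------------------------------------------------------------------------
# gradient checks
# ---------------------------------------------------------------------------

def numerical_grad(model, X, mask, Y, name, idx, eps=1e-6):
    p = model.params[name]
    orig = p[idx]
    p[idx] = orig + eps
    lp, _ = model.loss_and_grads(X, mask, Y)
    p[idx] = orig - eps
    lm, _ = model.loss_and_grads(X, mask, Y)
    p[idx] = orig
    return (lp - lm) / (2 * eps)


@pytest.mark.parametrize("cls,kwargs", [
    (RecurrentTagger, dict(embed_dim=6, hidden_dim=5)),
    (ConvTagger, dict(embed_dim=6, channels=5)),
    (TransformerTagger, dict(model_dim=8, n_layers=2, n_heads=2,
                             ff_dim=12, max_len=16)),
])
def test_backprop_matches_finite_differences(cls, kwargs, rng):
    """Analytic gradients of every parameter agree with central
    differences on a tiny random batch (ragged lengths, padded)."""
    entries = [f"t{i}" for i in range(12)] + ["[UNK]"]
    model = cls(entries, seed=3, **kwargs)
    seqs = [["t1", "t2", "t3", "t4"], ["t5", "t6"], ["t7"]]
    X, mask = model.pad_batch(seqs)
    Y = rng.integers(0, 4, X.shape)
    _, grads = model.loss_and_grads(X, mask, Y)
    for name, g in grads.items():
        flat = np.argsort(np.abs(g), axis=None)[-3:]  # largest entries
        for f in flat:
            idx = np.unravel_index(f, g.shape)
            num = numerical_grad(model, X, mask, Y, name, idx)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-7), name


class TestTrainNeural:
    def test_zero_epochs_returns_initialized_model(self, tokenized, vocab):
        m0 = train_neural(tokenized[:10], config=TrainConfig(epochs=0,
                                                             seed=5),
                          vocab=vocab)
        m1 = RecurrentTagger(vocab.entries, seed=5)
        for k in m1.params:
            assert np.array_equal(m0.params[k], m1.params[k])
        assert m0.history == []

    def test_loss_decreases_on_separable_data(self, tokenized, vocab):
        model = train_neural(tokenized[:100],
                             config=TrainConfig(epochs=5, seed=1),
                             vocab=vocab)
        assert all(np.isfinite(model.history))
        assert model.history[-1] < model.history[0]

    def test_unknown_architecture_rejected(self, tokenized, vocab):
        with pytest.raises(CapabilityError):
            train_neural(tokenized[:5], architecture="quantum",
                         vocab=vocab)

    def test_recurrent_learns_separable_task(self, tokenized, vocab):
        """Token tagging accuracy on held-out separable statements is high
        after training (every token string maps to one class)."""
        train, test = tokenized[:400], tokenized[400:500]
        model = train_neural(
            train, config=TrainConfig(epochs=12, seed=0,
                                      learning_rate=3e-3), vocab=vocab)
        correct = total = 0
        for st in test:
            if not st.tokens:
                continue
            pred = predict(model, st).argmax(axis=1)
            correct += int((pred == np.array(st.token_tags)).sum())
            total += len(st.tokens)
        assert correct / total >= 0.97

    def test_save_load_round_trip(self, tmp_path, tokenized, vocab):
        model = train_neural(tokenized[:30],
                             config=TrainConfig(epochs=1, seed=2),
                             vocab=vocab)
        save_model(model, tmp_path / "m", vocab=vocab)
        back = load_model(tmp_path / "m")
        st = tokenized[0]
        assert np.allclose(predict(model, st), predict(back, st))


class TestNSPCorpus:
    def _reports(self, n_reports=30, stmts=3, width=5):
        return [[[f"r{r}s{k}t{j}" for j in range(width)]
                 for k in range(stmts)] for r in range(n_reports)]

    def test_minimum_pairs_ratio(self):
        pairs = make_nsp_corpus(self._reports(), 3, seed=0)
        labels = [p.label for p in pairs]
        assert labels.count("IsNext") == 1
        assert labels.count("NotNext") == 2

    def test_exact_third_for_multiples_of_three(self):
        pairs = make_nsp_corpus(self._reports(), 9000, seed=1)
        assert sum(p.is_next for p in pairs) == 3000

    def test_is_next_pairs_are_adjacent_same_report(self):
        pairs = make_nsp_corpus(self._reports(), 300, seed=2)
        for p in pairs:
            a, b = p.first[0], p.second[0]
            ra, ka = a[1:].split("s")[0], int(a.split("s")[1][0])
            rb, kb = b[1:].split("s")[0], int(b.split("s")[1][0])
            if p.is_next:
                assert ra == rb and kb == ka + 1
            else:
                assert not (ra == rb and abs(kb - ka) == 1)

    def test_deterministic_under_seed(self):
        a = make_nsp_corpus(self._reports(), 60, seed=9)
        b = make_nsp_corpus(self._reports(), 60, seed=9)
        assert a == b

    def test_error_contracts(self):
        with pytest.raises(ConfigurationError):
            make_nsp_corpus(self._reports(), 2, seed=0)
        with pytest.raises(ConfigurationError, match="consecutive"):
            make_nsp_corpus([[["a"]], [["b"]]], 3, seed=0)
        with pytest.raises(ValueError):
            NSPPair((), ("x",), "IsNext")
        with pytest.raises(ValueError):
            NSPPair(("x",), ("y",), "Maybe")


class TestPretrainNSP:
    def test_zero_threshold_stops_after_first_batch(self, vocab):
        reports = [[[f"w{r}a", f"w{r}b"], [f"w{r}a", f"w{r}c"]]
                   for r in range(10)]
        pairs = make_nsp_corpus(reports, 30, seed=0)
        tagger = RecurrentTagger(vocab.entries, seed=0)
        _, result = pretrain_nsp(tagger, pairs, accuracy_threshold=0.0,
                                 max_steps=100, seed=0)
        assert result.steps == 1
        assert result.reached

    def test_marker_token_task_reaches_threshold(self):
        """IsNext pairs share a marker token, so the task is separable and
        the loop must reach its 99% stopping criterion."""
        rng = np.random.default_rng(0)
        entries = [f"w{i}" for i in range(50)] + ["MARK", "[UNK]"]
        pairs = []
        for i in range(900):
            a = [f"w{rng.integers(50)}" for _ in range(4)]
            b = [f"w{rng.integers(50)}" for _ in range(4)]
            if i % 3 == 0:
                a[0] = b[0] = "MARK"
                pairs.append(NSPPair(tuple(a), tuple(b), "IsNext"))
            else:
                pairs.append(NSPPair(tuple(a), tuple(b), "NotNext"))
        tagger = RecurrentTagger(entries, embed_dim=16, hidden_dim=32,
                                 seed=1)
        _, result = pretrain_nsp(tagger, pairs, accuracy_threshold=0.99,
                                 max_steps=4000, seed=1)
        assert result.reached
        assert result.accuracy >= 0.99

    def test_unreached_threshold_warns_and_flags(self):
        rng = np.random.default_rng(3)
        entries = [f"w{i}" for i in range(20)] + ["[UNK]"]
        # labels independent of content: accuracy cannot hit 1.0
        pairs = [NSPPair(tuple(f"w{rng.integers(20)}" for _ in range(3)),
                         tuple(f"w{rng.integers(20)}" for _ in range(3)),
                         "IsNext" if i % 3 == 0 else "NotNext")
                 for i in range(300)]
        tagger = RecurrentTagger(entries, embed_dim=8, hidden_dim=8,
                                 seed=0)
        with pytest.warns(UserWarning, match="max_steps"):
            _, result = pretrain_nsp(tagger, pairs,
                                     accuracy_threshold=1.0, max_steps=30,
                                     seed=0)
        assert not result.reached
        assert result.steps == 30

    def test_tagging_head_untouched_by_pretraining(self, vocab):
        reports = [[[f"w{r}a", f"w{r}b"], [f"w{r}a", f"w{r}c"]]
                   for r in range(10)]
        pairs = make_nsp_corpus(reports, 30, seed=0)
        tagger = RecurrentTagger(vocab.entries, seed=4)
        before = {k: tagger.params[k].copy() for k in ("Wo", "bo")}
        pre, _ = pretrain_nsp(tagger, pairs, accuracy_threshold=0.1,
                              max_steps=20, seed=0)
        for k in ("Wo", "bo"):
            assert np.array_equal(pre.params[k], before[k])
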