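import numpy as np
import pytest

from nimo.corpus import SPECIALS, Vocabulary, build_vocabulary, make_sentence
from nimo.generator import (
    BeamConfig,
    GeneratorError,
    GeneratorModel,
    ModelConfig,
    Transformer,
    attention,
    beam_search,
    causal_mask,
    log_softmax,
    sample_molecules,
    sample_sequences,
    train,
)

TINY = ModelConfig(d_model=16, n_heads=2, n_layers=1, d_ff=32, max_len=10, dropout=0.0, seed=0)


def toy_vocab(tokens=("A", "B", "C")):
    v = Vocabulary()
    for t in SPECIALS:
        v.add(t)
    v.add("<att:1>")
    for t in tokens:
        v.add(t)
    return v


def toy_model(seed=0, config=None, tokens=("A", "B", "C")):
    v = toy_vocab(tokens)
    cfg = config or ModelConfig(**{**TINY.__dict__, "seed": seed})
    return GeneratorModel(config=cfg, vocab=v, net=Transformer(len(v), cfg))


class TestAttention:
    def test_zero_query_averages_visible_values(self):
        v = np.arange(12.0).reshape(4, 3)
        q = np.zeros((4, 2))
        k = np.random.default_rng(0).normal(size=(4, 2))
        out, w = attention(q, k, v, causal_mask(4))
        for i in range(4):
            assert np.allclose(out[i], v[: i + 1].mean(axis=0))
            assert np.allclose(w[i, : i + 1], 1.0 / (i + 1))

    def test_single_visible_position_copies_value(self):
        rng = np.random.default_rng(1)
        q, k, v = rng.normal(size=(3, 2, 4))
        out, _ = attention(q, k, v, causal_mask(2))
        assert np.allclose(out[0], v[0])

    def test_two_by_two_hand_case(self):
        # d_k = 1: scores s_ij = q_i * k_j; row softmax then mix v
        q = np.array([[1.0], [2.0]])
        k = np.array([[0.5], [-0.5]])
        v = np.array([[1.0], [3.0]])
        out, w = attention(q, k, v)
        s = q @ k.T
        ref = np.exp(s) / np.exp(s).sum(axis=1, keepdims=True)
        assert np.allclose(w, ref)
        assert np.allclose(out, ref @ v)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        q, k, v = rng.normal(size=(3, 5, 4))
        _, w = attention(q, k, v, causal_mask(5))
        assert np.allclose(w.sum(-1), 1.0)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(d_model=8, n_heads=2, n_layers=2, d_ff=12, max_len=6,
                          dropout=0.0, seed=1)
        net = Transformer(7, cfg)
        ids = np.array([[1, 4, 5, 6, 2], [1, 5, 4, 2, 0]])
        tg = np.array([[4, 5, 6, 2, 0], [5, 4, 2, 0, 0]])
        mask = np.array([[1, 1, 1, 1, 0], [1, 1, 1, 0, 0.0]])
        _, grads = net.loss_and_grads(ids, tg, mask)
        rng = np.random.default_rng(0)
        for key in ("emb", "w_out", "l0.wq", "l0.w1", "l1.wo", "l1.ln2.g", "l0.bv"):
            p = net.params[key]
            for flat in rng.choice(p.size, size=min(3, p.size), replace=False):
                mi = np.unravel_index(flat, p.shape)
                eps, orig = 1e-6, p[mi]
                p[mi] = orig + eps
                l1, _ = net.loss_and_grads(ids, tg, mask)
                p[mi] = orig - eps
                l2, _ = net.loss_and_grads(ids, tg, mask)
                p[mi] = orig
                num = (l1 - l2) / (2 * eps)
                assert grads[key][mi] == pytest.approx(num, abs=1e-7, rel=1e-5)

    def test_causal_mask_blocks_future_tokens(self):
        model = toy_model()
        a = np.array([[4, 5, 6, 5]])
        b = np.array([[4, 5, 7, 5]])  # change only position 2
        la, _ = model.net.forward(a)
        lb, _ = model.net.forward(b)
        assert np.allclose(la[0, :2], lb[0, :2])
        assert not np.allclose(la[0, 2:], lb[0, 2:])


class TestTraining:
    def sentences(self):
        rng = np.random.default_rng(5)
        motifs = ["A", "B", "C"]
        return [
            make_sentence([f"c{i}"], [motifs[j] for j in rng.integers(0, 3, 3)])
            for i in range(6)
        ]

    def test_untrained_nll_near_uniform(self):
        sents = self.sentences()
        vocab = build_vocabulary(sents)
        model = train(sents, vocab, ModelConfig(**{**TINY.__dict__, "max_len": 12}),
                      epochs=0 + 1, lr=0.0)
        assert model.training_log[-1][1] == pytest.approx(np.log(len(vocab)), rel=0.05)

    def test_training_reduces_loss_and_is_deterministic(self):
        sents = self.sentences()
        vocab = build_vocabulary(sents)
        cfg = ModelConfig(d_model=32, n_heads=4, n_layers=2, d_ff=64, max_len=12,
                          dropout=0.0, seed=3)
        m1 = train(sents, vocab, cfg, epochs=40, lr=3e-3, seed=3)
        m2 = train(sents, vocab, cfg, epochs=40, lr=3e-3, seed=3)
        assert m1.training_log == m2.training_log
        assert m1.training_log[-1][1] < m1.training_log[0][1]

    def test_empty_corpus_and_overlong_sentence(self):
        with pytest.raises(GeneratorError):
            train([], toy_vocab(), TINY)
        long = make_sentence(["c"], ["A"] * 30)
        with pytest.raises(GeneratorError):
            train([long], build_vocabulary([long]), TINY)

    def test_save_load_roundtrip(self, tmp_path):
        sents = self.sentences()
        vocab = build_vocabulary(sents)
        model = train(sents, vocab, ModelConfig(**{**TINY.__dict__, "max_len": 12}),
                      epochs=3, lr=1e-3)
        model.save(tmp_path / "model")
        loaded = GeneratorModel.load(tmp_path / "model")
        ids = [vocab.encode(list(sents[0].tokens[:3]))]
        assert np.allclose(model.next_logprobs(ids), loaded.next_logprobs(ids))
        assert loaded.training_log == model.training_log


class TestBeamSearch:
    def test_beam_width_one_equals_greedy_rollout(self):
        model = toy_model(seed=4)
        res = beam_search(model, [], "<att:1>", BeamConfig(beam_width=1, n_return=1))
        toks, score, _ = res[0]
        v = model.vocab
        hyp = v.encode(["<att:1>", "<bos>"])
        greedy, total = [], 0.0
        banned = {v.pad_id, v.bos_id, v.token_to_id["<unk>"]}
        while len(hyp) < model.config.max_len:
            lp = model.next_logprobs([hyp])[0]
            lp[list(banned)] = -np.inf
            tok = int(np.argmax(lp))
            total += lp[tok]
            hyp.append(tok)
            if tok == v.eos_id:
                break
            greedy.append(v.id_to_token[tok])
        assert list(toks) == greedy
        assert score == pytest.approx(total)

    def test_scores_are_nonpositive_and_sorted(self):
        model = toy_model(seed=6)
        res = beam_search(model, [], "<att:1>", BeamConfig(beam_width=4, n_return=4))
        scores = [s for _t, s, _f in res]
        assert all(s <= 0 for s in scores)
        assert scores == sorted(scores, reverse=True)

    def test_seed_prefix_respected(self):
        model = toy_model(seed=7)
        res = beam_search(model, [], "<att:1>",
                          BeamConfig(beam_width=3, n_return=3), seed_prefix=["B"])
        for toks, _s, _f in res:
            assert toks[0] == "B"

    def test_unknown_seed_token_rejected(self):
        model = toy_model()
        with pytest.raises(GeneratorError):
            beam_search(model, [], "<att:1>", seed_prefix=["ZZZ"])

    def test_banned_tokens_never_sampled(self):
        model = toy_model(seed=8)
        beam = BeamConfig(beam_width=3, n_return=3, banned_tokens=frozenset({"A"}))
        for toks, _s, _f in beam_search(model, [], "<att:1>", beam):
            assert "A" not in toks

    def test_beam_equals_exhaustive_enumeration(self):
        # tiny vocab, 3 generation steps: beam wide enough to cover the
        # whole search tree must match brute-force argmax
        for seed in range(5):
            model = toy_model(seed=seed)
            v = model.vocab
            prefix = v.encode(["<att:1>", "<bos>"])
            res = beam_search(model, [], "<att:1>",
                              BeamConfig(beam_width=4 ** 3, n_return=1),
                              max_len=len(prefix) + 3)
            best = _enumerate_best(model, prefix, steps=3)
            assert res[0][1] == pytest.approx(best, abs=1e-9)


def _enumerate_best(model, prefix, steps):
    v = model.vocab
    allowed = [
        i for i in range(len(v))
        if i not in (v.pad_id, v.bos_id, v.token_to_id["<unk>"])
    ]
    best = -np.inf

    def rec(hyp, score, depth):
        nonlocal best
        if depth == steps:
            best = max(best, score)
            return
        lp = model.next_logprobs([hyp])[0]
        for t in allowed:
            if t == v.eos_id:
                best = max(best, score + lp[t])
            else:
                rec(hyp + [t], score + lp[t], depth + 1)

    rec(list(prefix), 0.0, 0)
    return best


class TestSampling:
    def test_zero_samples(self):
        assert sample_molecules(toy_model(), [], 0) == []

    def test_overfit_model_reproduces_training_molecules(self):
        from nimo.fragmenter import fragment
        from nimo.sequence import canonicalize

        smis = ["CC1CCCCC1", "CCc1ccccc1", "OC1CCCC1"]
        sents = [
            make_sentence([f"c{i}"], canonicalize(fragment(s, "m")).tokens)
            for i, s in enumerate(smis)
        ]
        vocab = build_vocabulary(sents)
        cfg = ModelConfig(d_model=48, n_heads=4, n_layers=2, d_ff=96, max_len=12,
                          dropout=0.0, seed=0)
        model = train(sents, vocab, cfg, epochs=150, lr=3e-3)
        out = sample_molecules(model, ["c0"], 5, BeamConfig(beam_width=2),
                               temperature=0.3, seed=1,
                               info_tokens=[sents[0].tokens[1]])
        valid = [r for r in out if r["valid"]]
        assert len(valid) / len(out) >= 0.9
        from rdkit import Chem

        assert Chem.CanonSmiles(smis[0]) in {r["smiles"] for r in valid}

    def test_sample_sequences_deterministic_given_seed(self):
        model = toy_model(seed=9)
        a = sample_sequences(model, [], "<att:1>", 4, seed=5)
        b = sample_sequences(model, [], "<att:1>", 4, seed=5)
        assert a == b


def test_logsoftmax_normalizes():
    x = np.random.default_rng(0).normal(size=(3, 7)) * 10
    assert np.allclose(np.exp(log_softmax(x)).sum(-1), 1.0)
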