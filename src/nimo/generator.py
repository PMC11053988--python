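"""Conditional decoder-only transformer over motif sentences.

The model is a standard causal transformer decoder: token embedding plus
sinusoidal positional encoding, stacked blocks of masked multi-head
scaled-dot-product self-attention (``softmax(QK^T/sqrt(d_k))V``) and a
ReLU feed-forward network, each followed by a residual connection and
layer normalization, then a linear+softmax head over the vocabulary.
Conditioning is purely positional: the property-constraint labels and
the motif-info token are ordinary tokens at the start of the sequence,
visible to every later position through the causal mask but never used
as training targets. Training minimizes the next-token negative
log-likelihood summed over the motif positions and <eos>.

Implemented directly on NumPy (float64) with hand-derived gradients and
Adam; the intended scale is desk-size corpora on one CPU, and the
gradient implementation is verified against finite differences in the
test suite.

Sampling is beam search: keep the K highest accumulated-log-probability
hypotheses per step until every beam emits <eos> or the step budget T is
reached, so at most T*K*|V| candidate expansions are ever scored.
Specials can be banned, repeats suppressed, and a scaffold or motif
prefix can seed the beam. For bulk sampling a temperature-controlled
stochastic variant draws among the top-K continuations so one model can
emit many distinct molecules.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import Vocabulary, make_sentence


class GeneratorError(ValueError):
    pass


@dataclass
class ModelConfig:
    d_model: int = 256
    n_heads: int = 8
    n_layers: int = 4
    d_ff: int = 1024
    max_len: int = 64
    dropout: float = 0.1
    seed: int = 0

    @property
    def d_k(self) -> int:
        if self.d_model % self.n_heads:
            raise GeneratorError("d_model must be a multiple of n_heads")
        return self.d_model // self.n_heads


@dataclass
class BeamConfig:
    beam_width: int = 16
    n_return: int = 1
    banned_tokens: frozenset = frozenset()
    no_repeat: bool = False

    def __post_init__(self):
        if not (1 <= self.n_return <= self.beam_width):
            raise GeneratorError("need 1 <= n_return <= beam_width")


def sinusoidal_encoding(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def _softmax(x, axis=-1):
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    x = x - x.max(axis=axis, keepdims=True)
    return x - np.log(np.exp(x).sum(axis=axis, keepdims=True))


def attention(q, k, v, mask=None):
    """Scaled dot-product attention: ``softmax(QK^T/sqrt(d_k) + mask)V``.

    ``mask`` is additive (0 for visible, -inf for hidden positions) and
    broadcasts against the score matrix. Returns (output, weights); each
    weight row sums to 1 over the visible positions, so every output row
    is a convex combination of rows of V.
    """
    dk = q.shape[-1]
    s = q @ np.swapaxes(k, -1, -2) / np.sqrt(dk)
    if mask is not None:
        s = s + mask
    w = _softmax(s)
    return w @ v, w


def causal_mask(n: int) -> np.ndarray:
    return np.triu(np.full((n, n), -np.inf), k=1)


_LN_EPS = 1e-5


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _ln_backward(dy, g, cache):
    xhat, inv = cache
    n = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv / n * (
        n * dxhat
        - dxhat.sum(-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(-1, keepdims=True)
    )
    return dx, dg, db


class Transformer:
    """Parameter container + forward/backward passes."""

    def __init__(self, vocab_size: int, config: ModelConfig):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        d, h, dff = config.d_model, config.n_heads, config.d_ff
        scale = 0.02

        def w(*shape):
            return rng.normal(0.0, scale, shape)

        p = {"emb": w(vocab_size, d), "w_out": w(d, vocab_size),
             "b_out": np.zeros(vocab_size)}
        for l in range(config.n_layers):
            for name in ("q", "k", "v", "o"):
                p[f"l{l}.w{name}"] = w(d, d)
                p[f"l{l}.b{name}"] = np.zeros(d)
            p[f"l{l}.w1"] = w(d, dff)
            p[f"l{l}.b1"] = np.zeros(dff)
            p[f"l{l}.w2"] = w(dff, d)
            p[f"l{l}.b2"] = np.zeros(d)
            for ln in ("ln1", "ln2"):
                p[f"l{l}.{ln}.g"] = np.ones(d)
                p[f"l{l}.{ln}.b"] = np.zeros(d)
        self.params = p
        self.pe = sinusoidal_encoding(config.max_len, d)

    # -- forward ----------------------------------------------------------

    def forward(self, ids: np.ndarray, train: bool = False, rng=None):
        """ids (B,L) int -> logits (B,L,V); caches activations if train."""
        p, cfg = self.params, self.config
        B, L = ids.shape
        if L > cfg.max_len:
            raise GeneratorError("sentence_exceeds_T")
        d, H, dk = cfg.d_model, cfg.n_heads, cfg.d_k
        drop = cfg.dropout if train else 0.0
        causal = causal_mask(L)
        h = p["emb"][ids] + self.pe[:L]
        cache = {"ids": ids, "drop": []}

        def dropout(x):
            if drop <= 0:
                cache["drop"].append(None)
                return x
            m = (rng.random(x.shape) >= drop) / (1.0 - drop)
            cache["drop"].append(m)
            return x * m

        for l in range(cfg.n_layers):
            c = {}
            c["x_in"] = h
            q = h @ p[f"l{l}.wq"] + p[f"l{l}.bq"]
            k = h @ p[f"l{l}.wk"] + p[f"l{l}.bk"]
            v = h @ p[f"l{l}.wv"] + p[f"l{l}.bv"]
            qh = q.reshape(B, L, H, dk).transpose(0, 2, 1, 3)
            kh = k.reshape(B, L, H, dk).transpose(0, 2, 1, 3)
            vh = v.reshape(B, L, H, dk).transpose(0, 2, 1, 3)
            oh, w_att = attention(qh, kh, vh, causal)
            o = oh.transpose(0, 2, 1, 3).reshape(B, L, d)
            a = dropout(o @ p[f"l{l}.wo"] + p[f"l{l}.bo"])
            h1, lnc1 = _ln_forward(h + a, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            z1 = h1 @ p[f"l{l}.w1"] + p[f"l{l}.b1"]
            r1 = np.maximum(z1, 0.0)
            f = dropout(r1 @ p[f"l{l}.w2"] + p[f"l{l}.b2"])
            h2, lnc2 = _ln_forward(h1 + f, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            c.update(qh=qh, kh=kh, vh=vh, w_att=w_att, o=o, h1=h1,
                     z1=z1, r1=r1, lnc1=lnc1, lnc2=lnc2)
            cache[f"l{l}"] = c
            h = h2
        cache["h_final"] = h
        logits = h @ p["w_out"] + p["b_out"]
        return logits, cache

    # -- loss + gradients --------------------------------------------------

    def loss_and_grads(self, ids, targets, mask, train=True, rng=None):
        """Mean NLL (nats per counted target token) and parameter grads.

        ``targets`` (B,L) holds the next token per position; ``mask``
        (B,L) selects the positions that contribute to the loss.
        """
        p, cfg = self.params, self.config
        logits, cache = self.forward(ids, train=train, rng=rng)
        B, L, V = logits.shape
        lp = log_softmax(logits)
        n_tok = mask.sum()
        if n_tok == 0:
            raise GeneratorError("no target tokens under the loss mask")
        picked = np.take_along_axis(lp, targets[..., None], axis=-1)[..., 0]
        loss = -(picked * mask).sum() / n_tok

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = np.exp(lp)
        onehot_sub = np.zeros_like(dlogits)
        np.put_along_axis(onehot_sub, targets[..., None], 1.0, axis=-1)
        dlogits = (dlogits - onehot_sub) * mask[..., None] / n_tok

        h = cache["h_final"]
        grads["w_out"] = h.reshape(-1, cfg.d_model).T @ dlogits.reshape(-1, V)
        grads["b_out"] = dlogits.sum((0, 1))
        dh = dlogits @ p["w_out"].T

        d, H, dk = cfg.d_model, cfg.n_heads, cfg.d_k
        drops = cache["drop"]
        for l in reversed(range(cfg.n_layers)):
            c = cache[f"l{l}"]
            dz2, dg, db = _ln_backward(dh, p[f"l{l}.ln2.g"], c["lnc2"])
            grads[f"l{l}.ln2.g"] = dg
            grads[f"l{l}.ln2.b"] = db
            df = dz2.copy()
            m = drops[2 * l + 1]
            if m is not None:
                df = df * m
            grads[f"l{l}.w2"] = c["r1"].reshape(-1, cfg.d_ff).T @ df.reshape(-1, d)
            grads[f"l{l}.b2"] = df.sum((0, 1))
            dr1 = df @ p[f"l{l}.w2"].T
            dz1 = dr1 * (c["z1"] > 0)
            grads[f"l{l}.w1"] = c["h1"].reshape(-1, d).T @ dz1.reshape(-1, cfg.d_ff)
            grads[f"l{l}.b1"] = dz1.sum((0, 1))
            dh1 = dz2 + dz1 @ p[f"l{l}.w1"].T
            dz0, dg, db = _ln_backward(dh1, p[f"l{l}.ln1.g"], c["lnc1"])
            grads[f"l{l}.ln1.g"] = dg
            grads[f"l{l}.ln1.b"] = db
            da = dz0.copy()
            m = drops[2 * l]
            if m is not None:
                da = da * m
            grads[f"l{l}.wo"] = c["o"].reshape(-1, d).T @ da.reshape(-1, d)
            grads[f"l{l}.bo"] = da.sum((0, 1))
            do = da @ p[f"l{l}.wo"].T
            doh = do.reshape(B, L, H, dk).transpose(0, 2, 1, 3)
            dw_att = doh @ c["vh"].transpose(0, 1, 3, 2)
            dvh = c["w_att"].transpose(0, 1, 3, 2) @ doh
            w_att = c["w_att"]
            ds = w_att * (dw_att - (dw_att * w_att).sum(-1, keepdims=True))
            ds = ds / np.sqrt(dk)
            dqh = ds @ c["kh"]
            dkh = ds.transpose(0, 1, 3, 2) @ c["qh"]
            x_in = c["x_in"]
            dx = dz0
            for name, dmat in (("q", dqh), ("k", dkh), ("v", dvh)):
                dflat = dmat.transpose(0, 2, 1, 3).reshape(B, L, d)
                grads[f"l{l}.w{name}"] = x_in.reshape(-1, d).T @ dflat.reshape(-1, d)
                grads[f"l{l}.b{name}"] = dflat.sum((0, 1))
                dx = dx + dflat @ p[f"l{l}.w{name}"].T
            dh = dx
        np.add.at(grads["emb"], cache["ids"], dh)
        return loss, grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class GeneratorModel:
    config: ModelConfig
    vocab: Vocabulary
    net: Transformer
    training_log: list = field(default_factory=list)  # (epoch, mean NLL)

    # -- persistence ------------------------------------------------------

    def save(self, model_dir: str):
        os.makedirs(model_dir, exist_ok=True)
        with open(os.path.join(model_dir, "config.json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        self.vocab.save(os.path.join(model_dir, "vocab.tsv"))
        np.savez(os.path.join(model_dir, "params.npz"), **self.net.params)
        with open(os.path.join(model_dir, "training_log.csv"), "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "nll"])
            wr.writerows(self.training_log)

    @classmethod
    def load(cls, model_dir: str):
        with open(os.path.join(model_dir, "config.json")) as fh:
            config = ModelConfig(**json.load(fh))
        vocab = Vocabulary.load(os.path.join(model_dir, "vocab.tsv"))
        net = Transformer(len(vocab), config)
        with np.load(os.path.join(model_dir, "params.npz")) as arrs:
            net.params = {k: arrs[k] for k in arrs.files}
        log = []
        path = os.path.join(model_dir, "training_log.csv")
        if os.path.exists(path):
            with open(path) as fh:
                rd = csv.reader(fh)
                next(rd, None)
                log = [(int(e), float(v)) for e, v in rd]
        return cls(config=config, vocab=vocab, net=net, training_log=log)

    # -- scoring ----------------------------------------------------------

    def next_logprobs(self, prefixes: list[list[int]]) -> np.ndarray:
        """Log p(next token) for each prefix; (n_prefix, V)."""
        L = max(len(p) for p in prefixes)
        pad = self.vocab.pad_id
        ids = np.full((len(prefixes), L), pad, dtype=np.int64)
        for i, pre in enumerate(prefixes):
            ids[i, : len(pre)] = pre
        logits, _ = self.net.forward(ids, train=False)
        rows = logits[np.arange(len(prefixes)), [len(p) - 1 for p in prefixes]]
        return log_softmax(rows, axis=-1)


def _encode_corpus(sentences, vocab: Vocabulary, max_len: int):
    """Pack sentences into (ids, targets, mask) arrays for training."""
    pad, bos = vocab.pad_id, vocab.bos_id
    enc = [vocab.encode(s.tokens if hasattr(s, "tokens") else s) for s in sentences]
    for e in enc:
        if len(e) > max_len:
            raise GeneratorError("sentence_exceeds_T")
    L = max(len(e) for e in enc)
    ids = np.full((len(enc), L), pad, dtype=np.int64)
    targets = np.full((len(enc), L), pad, dtype=np.int64)
    mask = np.zeros((len(enc), L))
    for i, e in enumerate(enc):
        ids[i, : len(e)] = e
        targets[i, : len(e) - 1] = e[1:]
        bos_pos = e.index(bos)
        for j in range(len(e) - 1):
            if j + 1 > bos_pos:  # motif tokens and <eos> only
                mask[i, j] = 1.0
    return ids, targets, mask


def train(
    sentences,
    vocab: Vocabulary,
    config: ModelConfig | None = None,
    epochs: int = 300,
    lr: float = 1e-3,
    batch_size: int | None = None,
    warmup: int = 20,
    seed: int | None = None,
    verbose: bool = False,
) -> GeneratorModel:
    """Fit the conditional transformer by next-token NLL with Adam.

    Deterministic for a fixed (corpus, config, seed). Returns the model
    with its per-epoch mean NLL log.
    """
    sentences = list(sentences)
    if not sentences:
        raise GeneratorError("empty_corpus")
    config = config or ModelConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    net = Transformer(len(vocab), config)
    ids, targets, mask = _encode_corpus(sentences, vocab, config.max_len)
    n = ids.shape[0]
    batch_size = batch_size or n
    mom = {k: np.zeros_like(v) for k, v in net.params.items()}
    vel = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    log = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        tot_loss, tot_tok = 0.0, 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            step += 1
            loss, grads = net.loss_and_grads(
                ids[idx], targets[idx], mask[idx], train=True, rng=rng
            )
            ntok = mask[idx].sum()
            tot_loss += loss * ntok
            tot_tok += ntok
            cur_lr = lr * min(1.0, step / max(warmup, 1))
            for k, g in grads.items():
                mom[k] = b1 * mom[k] + (1 - b1) * g
                vel[k] = b2 * vel[k] + (1 - b2) * g * g
                mhat = mom[k] / (1 - b1**step)
                vhat = vel[k] / (1 - b2**step)
                net.params[k] -= cur_lr * mhat / (np.sqrt(vhat) + eps)
        log.append((epoch, tot_loss / tot_tok))
        if verbose and (epoch % 25 == 0 or epoch == 1):
            print(f"epoch {epoch:4d}  nll {log[-1][1]:.4f}")
    return GeneratorModel(config=config, vocab=vocab, net=net, training_log=log)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _allowed_mask(model, beam: BeamConfig, hyp, prefix_len):
    v = model.vocab
    banned = set(v.encode(list(beam.banned_tokens))) if beam.banned_tokens else set()
    banned.update((v.pad_id, v.bos_id, v.token_to_id["<unk>"]))
    if beam.no_repeat:
        banned.update(t for t in hyp[prefix_len:] if t != v.eos_id)
    mask = np.zeros(len(v))
    if banned:
        mask[list(banned)] = -np.inf
    return mask


def beam_search(
    model: GeneratorModel,
    constraint,
    motif_info: str,
    beam: BeamConfig | None = None,
    seed_prefix=None,
    max_len: int | None = None,
):
    """Top-N motif sequences by accumulated log-probability.

    ``constraint`` is a ConstraintCode or label iterable; ``motif_info``
    the info token string; ``seed_prefix`` optional motif tokens forced
    at the start of generation (scaffold seeding). Returns a list of
    (motif tokens, score, terminated) sorted best first; ``terminated``
    is False for hypotheses cut off at the step budget.
    """
    beam = beam or BeamConfig()
    v = model.vocab
    labels = list(constraint)
    prefix_tokens = labels + [motif_info, "<bos>"] + list(seed_prefix or [])
    for t in prefix_tokens:
        if t not in v.token_to_id:
            raise GeneratorError(f"seed_token_unknown: {t!r}")
    prefix = v.encode(prefix_tokens)
    T = max_len or model.config.max_len
    active = [(0.0, tuple(prefix))]
    finished: list[tuple[float, tuple, bool]] = []
    while active and len(active[0][1]) < T:
        lps = model.next_logprobs([list(h) for _s, h in active])
        cand_scores, cand_meta = [], []
        for i, (score, hyp) in enumerate(active):
            lp = lps[i] + _allowed_mask(model, beam, hyp, len(prefix))
            for tok in range(len(v)):
                if np.isfinite(lp[tok]):
                    cand_scores.append(score + lp[tok])
                    cand_meta.append((i, tok))
        if not cand_scores:
            break
        cand_scores = np.asarray(cand_scores)
        order = np.lexsort(
            ([m[1] for m in cand_meta], [m[0] for m in cand_meta], -cand_scores)
        )
        new_active = []
        for j in order[: beam.beam_width]:
            score = float(cand_scores[j])
            i, tok = cand_meta[j]
            hyp = active[i][1] + (tok,)
            if tok == v.eos_id:
                finished.append((score, hyp, True))
            else:
                new_active.append((score, hyp))
        active = new_active
    finished.extend((s, h, False) for s, h in active)
    finished.sort(key=lambda x: (-x[0], x[1]))
    out = []
    for score, hyp, terminated in finished[: beam.n_return]:
        toks = [v.id_to_token[t] for t in hyp[len(prefix) - len(seed_prefix or []):]]
        toks = [t for t in toks if t != "<eos>"]
        out.append((tuple(toks), score, terminated))
    if not out:
        raise GeneratorError("no_terminated_hypothesis")
    return out


def sample_sequences(
    model: GeneratorModel,
    constraint,
    motif_info: str,
    n: int,
    beam: BeamConfig | None = None,
    temperature: float = 1.0,
    seed: int = 0,
    seed_prefix=None,
    max_len: int | None = None,
):
    """Stochastic top-K sampling: n sequences under one condition prefix."""
    beam = beam or BeamConfig()
    v = model.vocab
    labels = list(constraint)
    prefix_tokens = labels + [motif_info, "<bos>"] + list(seed_prefix or [])
    prefix = v.encode(prefix_tokens)
    T = max_len or model.config.max_len
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        hyp = list(prefix)
        terminated = False
        while len(hyp) < T:
            lp = model.next_logprobs([hyp])[0]
            lp = lp + _allowed_mask(model, beam, tuple(hyp), len(prefix))
            top = np.argsort(-lp, kind="stable")[: beam.beam_width]
            w = _softmax(lp[top] / max(temperature, 1e-6))
            tok = int(top[rng.choice(len(top), p=w)])
            hyp.append(tok)
            if tok == v.eos_id:
                terminated = True
                break
        toks = [v.id_to_token[t] for t in hyp[len(prefix) - len(seed_prefix or []):]]
        out.append((tuple(t for t in toks if t != "<eos>"), terminated))
    return out


def sample_molecules(
    model: GeneratorModel,
    constraint,
    n: int,
    beam: BeamConfig | None = None,
    temperature: float = 1.0,
    seed: int = 0,
    info_tokens=None,
    seed_prefix=None,
):
    """Sample n candidate molecules under a property constraint.

    Cycles over motif-info tokens seen in the vocabulary and draws
    stochastic top-K sequences, then reconstructs each one; entries that
    fail reconstruction come back with ``valid=False`` (the validity
    metric counts them). Returns a list of dicts
    {tokens, smiles, valid, reason}.
    """
    from .sequence import InvalidSequenceError, reconstruct

    if n <= 0:
        return []
    v = model.vocab
    if info_tokens is None:
        info_tokens = [t for t in v.id_to_token if t.startswith("<att:")]
        if not info_tokens:
            raise GeneratorError("vocabulary has no motif-info tokens")
    rng = np.random.default_rng(seed)
    results = []
    i = 0
    while len(results) < n:
        info = info_tokens[i % len(info_tokens)]
        i += 1
        take = min(n - len(results), 8)
        seqs = sample_sequences(
            model, constraint, info, take, beam=beam,
            temperature=temperature, seed=int(rng.integers(0, 2**31 - 1)),
            seed_prefix=seed_prefix,
        )
        for toks, terminated in seqs:
            rec = {"tokens": toks, "smiles": None, "valid": False, "reason": ""}
            if not terminated:
                rec["reason"] = "no_terminated_hypothesis"
            else:
                try:
                    rec["smiles"] = reconstruct(toks)
                    rec["valid"] = True
                except InvalidSequenceError as e:
                    rec["reason"] = e.reason
            results.append(rec)
    return results


def sentences_from_corpus(records, labeler=None):
    """Motif-corpus records -> Sentences, labeling each parent molecule.

    ``labeler`` maps a parent SMILES to constraint labels; default
    applies the descriptor thresholds of :mod:`nimo.corpus`.
    """
    from .corpus import assign_constraint_labels
    from .standardize import compute_descriptors

    if labeler is None:
        def labeler(smiles):
            return assign_constraint_labels(compute_descriptors(smiles))

    return [make_sentence(labeler(parent), motifs) for parent, motifs in records]
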