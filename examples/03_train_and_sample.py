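"""Train the conditional transformer on a toy corpus and sample from it.

Builds a two-class corpus whose classes use disjoint motif pools,
trains a small model, then samples under the class-A constraint and
reports how strongly the condition steers the motif choice.
"""

from nimo.corpus import build_vocabulary, info_token, make_sentence
from nimo.fixtures import generate_conditioned_toy_corpus
from nimo.generator import BeamConfig, ModelConfig, sample_molecules, train

corpus = generate_conditioned_toy_corpus(seed=0, per_class=150)
sentences = [make_sentence([f"class_{lab}"], toks) for lab, _p, toks in corpus.sentences]
vocab = build_vocabulary(sentences)
print(f"{len(sentences)} sentences, vocabulary of {len(vocab)} tokens")

config = ModelConfig(d_model=64, n_heads=4, n_layers=2, d_ff=128, max_len=24,
                     dropout=0.0, seed=0)
model = train(sentences, vocab, config, epochs=60, lr=2e-3, batch_size=64)
print(f"final training NLL: {model.training_log[-1][1]:.3f} nats/token")

samples = sample_molecules(model, ["class_A"], n=24,
                           beam=BeamConfig(beam_width=8), temperature=1.0,
                           seed=7, info_tokens=[info_token(2), info_token(3)])
n_valid = sum(s["valid"] for s in samples)
in_a = in_b = 0
for s in samples:
    for t in s["tokens"]:
        in_a += t in corpus.pools["A"]
        in_b += t in corpus.pools["B"]
print(f"{n_valid}/{len(samples)} sampled sequences reconstruct to molecules")
print(f"motif provenance: {in_a} class-A vs {in_b} class-B tokens")
# A well-conditioned model draws essentially all motifs from the pool of
# the requested class; invalid sequences feed the validity metric.
for s in samples[:5]:
    print(" ", s["smiles"] or f"invalid ({s['reason']})")
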