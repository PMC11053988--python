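"""Vocabulary building and conditioned training sentences.

A training sentence is::

    [constraint tokens] [motif-info token] <bos> motif ... motif <eos>

The constraint tokens are discrete property labels ("qed_good",
"logp_bad", "active", ...) derived from descriptor thresholds; the
motif-info token encodes the total number of attachment markers in the
motif sequence, bucketed to keep the vocabulary bounded. Constraint and
info positions are conditioning context: the model is never trained to
predict them, only the motif tokens and the terminal <eos>.

One token per motif: the vocabulary unit is the whole canonical motif
SMILES, not SMILES characters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)

INFO_MAX_EXACT = 12  # attachment counts 0..12 exact, then "13+"

# default "good" ranges, half-open [lo, hi); overridable via config
DEFAULT_THRESHOLDS = {
    "qed": {"good_range": [0.5, None]},
    "logp": {"good_range": [0.0, 5.0]},
    "sas": {"good_range": [None, 4.0]},
}

ACTIVITY_THRESHOLD = 44.36  # model-score cut: strictly above = active


class CorpusError(ValueError):
    pass


@dataclass(frozen=True)
class ConstraintCode:
    """Ordered discrete property labels prepended to a sentence."""

    labels: tuple

    def __iter__(self):
        return iter(self.labels)


def assign_constraint_labels(descriptors: dict, thresholds: dict | None = None) -> ConstraintCode:
    """Map a descriptor dict to good/bad labels, in fixed property order.

    Each property's config gives ``good_range`` = [lo, hi); None means
    unbounded on that side. A value exactly at ``lo`` is good, exactly at
    ``hi`` is not.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    labels = []
    for prop, cfg in thresholds.items():
        if prop not in descriptors:
            raise CorpusError(f"missing_descriptor: {prop}")
        v = descriptors[prop]
        lo, hi = cfg["good_range"]
        good = (lo is None or v >= lo) and (hi is None or v < hi)
        labels.append(f"{prop}_{'good' if good else 'bad'}")
    return ConstraintCode(tuple(labels))


def label_activity(score: float, threshold: float = ACTIVITY_THRESHOLD) -> str:
    """Binary activity label: strictly above the score threshold = active."""
    return "active" if score > threshold else "inactive"


_MARKER_RE = re.compile(r"\[[^\[\]]*\*[^\[\]]*\]|\*")


def count_attachment_points(motif_tokens) -> int:
    """Total number of attachment markers across the motif tokens."""
    return sum(len(_MARKER_RE.findall(t)) for t in motif_tokens)


def info_token(n_attach: int) -> str:
    if n_attach <= INFO_MAX_EXACT:
        return f"<att:{n_attach}>"
    return f"<att:{INFO_MAX_EXACT + 1}+>"


def all_info_tokens() -> list[str]:
    return [info_token(i) for i in range(INFO_MAX_EXACT + 2)]


@dataclass(frozen=True)
class Sentence:
    """One conditioned training example."""

    constraint: ConstraintCode
    motifs: tuple

    @property
    def tokens(self) -> tuple:
        return (
            tuple(self.constraint)
            + (info_token(count_attachment_points(self.motifs)), BOS)
            + tuple(self.motifs)
            + (EOS,)
        )


def make_sentence(constraint_labels, motif_tokens) -> Sentence:
    if isinstance(constraint_labels, ConstraintCode):
        code = constraint_labels
    else:
        code = ConstraintCode(tuple(constraint_labels))
    return Sentence(constraint=code, motifs=tuple(motif_tokens))


@dataclass
class Vocabulary:
    """Bijective token <-> id map with the four specials at the front."""

    token_to_id: dict = field(default_factory=dict)
    id_to_token: list = field(default_factory=list)

    def __len__(self):
        return len(self.id_to_token)

    def add(self, token: str) -> int:
        if token not in self.token_to_id:
            self.token_to_id[token] = len(self.id_to_token)
            self.id_to_token.append(token)
        return self.token_to_id[token]

    def encode(self, tokens) -> list[int]:
        unk = self.token_to_id[UNK]
        return [self.token_to_id.get(t, unk) for t in tokens]

    def decode(self, ids) -> list[str]:
        pad = self.token_to_id[PAD]
        return [self.id_to_token[i] for i in ids if i != pad]

    @property
    def pad_id(self):
        return self.token_to_id[PAD]

    @property
    def bos_id(self):
        return self.token_to_id[BOS]

    @property
    def eos_id(self):
        return self.token_to_id[EOS]

    @property
    def special_ids(self):
        return [self.token_to_id[t] for t in SPECIALS]

    def save(self, path):
        with open(path, "w") as fh:
            for i, t in enumerate(self.id_to_token):
                fh.write(f"{t}\t{i}\n")

    @classmethod
    def load(cls, path):
        v = cls()
        with open(path) as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                assert int(idx) == len(v.id_to_token)
                v.add(tok)
        return v


def build_vocabulary(sentences) -> Vocabulary:
    """Frequency-then-lexicographic token ids after the specials.

    Deterministic: the same corpus (in any order) yields the same map.
    """
    sentences = list(sentences)
    if not sentences:
        raise CorpusError("empty_corpus")
    counts: dict[str, int] = {}
    for s in sentences:
        toks = s.tokens if isinstance(s, Sentence) else s
        for t in toks:
            if t in SPECIALS:
                continue
            counts[t] = counts.get(t, 0) + 1
    vocab = Vocabulary()
    for t in SPECIALS:
        vocab.add(t)
    for t in sorted(counts, key=lambda t: (-counts[t], t)):
        vocab.add(t)
    return vocab


# ---------------------------------------------------------------------------
# corpus interchange format: one record per line,
# tab-separated: parent SMILES \t space-separated motif tokens
# ---------------------------------------------------------------------------

def write_motif_corpus(path, records):
    """records: iterable of (parent_smiles, motif token iterable)."""
    with open(path, "w") as fh:
        for parent, motifs in records:
            fh.write(parent + "\t" + " ".join(motifs) + "\n")


def read_motif_corpus(path):
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parent, motifs = line.split("\t")
            out.append((parent, tuple(motifs.split())))
    return out
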