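# Methods

## Standardization

Raw SMILES are desalted (RDKit `LargestFragmentChooser`, organic
fragment preferred), charge-neutralized with RDKit's `Uncharger`
(protonation/deprotonation where a neutral form is chemically valid;
atoms that cannot be neutralized without a valence violation stay
charged), and written as canonical, stereochemistry-preserving SMILES.
Unparseable input and empty post-desalt results are rejected with a
reason. Duplicates are removed on canonical SMILES, first occurrence
kept.

Glycoside trimming is *not* part of default standardization: there is
no published rule set we were prepared to commit to, and neither the
round trip nor generation depends on it. Sugar-bearing molecules simply
contribute pyranose motifs.

Descriptors: QED (RDKit), Crippen logP, Ertl–Schuffenhauer synthetic
accessibility (SAS, 1 = easy to 10 = hard, via the `sascorer` module
shipped with RDKit), molecular weight (g/mol), H-bond donor/acceptor
counts and rotatable bonds. All are pure functions of the canonical
SMILES.

## Fragmentation

**Motif rules (`m`).** Cut bonds are the union of (a) acyclic single
bonds with at least one ring-atom endpoint (ring/off-ring and
ring–ring connections) and (b) BRICS-cleavable bonds (full standard
RDKit BRICS table). A bond matching both rules is cut once. Ring bonds
are never cut.

**Scaffold rules (`s`).** Scaffold atoms are computed by iteratively
pruning terminal non-ring atoms; acyclic single bonds between a
scaffold atom and a non-scaffold atom are cut. Multiple bonds are never
cut, so exocyclic =O/=CH₂ appendages stay with the scaffold fragment,
consistent with the usual Bemis–Murcko convention. Acyclic molecules
have no scaffold and pass through as a flagged whole-molecule motif.

Every cut inserts a dummy-atom pair sharing a bond ID (the dummy's
isotope during fragmentation). IDs are assigned in ascending
(min, max) atom-index order over the canonical-order parent, making the
fragmentation a pure function of the canonical SMILES.

**Fused-edge separation (`sprime`).** After scaffold cuts, fused ring
systems are split at shared edges. A shared edge is eligible when it
lies in exactly two SSSR rings that share exactly its two atoms,
neither atom is in more than two rings (bridged systems are left
whole — bridged-ring transforms are out of scope, as are ring
opening/closing), and deleting the two atoms leaves exactly two
ring-containing components. The two shared atoms are duplicated into
both subrings; the canonically-first subring keeps them as *real*
atoms (tagged merge targets) while the other subring carries `[*]`
copies, including the shared bond itself. Reconstruction superposes
each copy onto its target. Keeping the elements on one side is what
makes the encoding lossless for hetero-fused systems; a representation
with dummies on both sides would forget the shared atoms' identity.
Fragments touched by edge surgery are kekulized (an excised aromatic
subring is not independently aromatic), and tetrahedral tags on the
junction atoms are dropped — ring-fusion stereochemistry is therefore
not preserved under `sprime`, while `m` and `s` keep full chirality at
cut points (the marker stands in for the departed neighbour).

Motif weight and heavy-atom size exclude markers: dummies are removed
and implicit hydrogens refill the open valences before weighing, so a
motif weighs what the corresponding capped fragment would.

## Canonical sequences and reconstruction

The fragments plus recorded cuts always form a tree: `m`/`s` cuts sever
acyclic bonds, and each fused-edge separation adds one node and one
edge. The canonical sequence is the DFS preorder of this tree rooted at
the fragment containing the parent's first canonical atom. Within a
fragment, connection "ports" are ordered by the fragment's own
canonical atom ranking (computed on a marker-neutral copy with
deterministic tie-breaking) and renumbered positionally as atom-map
numbers: map 1 (and 2 for a fused-edge pair) is the connection back to
the already-emitted part, higher maps are outgoing ports in rank order.
A single-bond port is a mapped dummy; a fused-edge port is a bonded
pair of mapped dummies on one side and a bonded pair of mapped real
atoms on the other — the token itself says which join is intended, so
decoding needs no out-of-band information.

Decoding replays the DFS with a stack: the first motif pushes its
outgoing ports (last first); each subsequent motif pops one port,
attaches through its map-1 port, and pushes its own outgoing ports.
Single-bond joins are delegated to RDKit `molzip`, which restores
tetrahedral stereo across the junction; fused-edge merges reattach the
copy's ring bonds to the target atoms (skipping the duplicated shared
bond) and recompute implicit hydrogens on the targets. Underflow,
leftovers or port-type mismatches raise `InvalidSequenceError`
(`dangling_marker` / `incompatible_fused_edge`); RDKit sanitization
failures surface as `valence_violation`. During sampling these
exceptions mark a sequence invalid rather than aborting the run.

Round-trip verification compares canonical SMILES with
stereochemistry stripped, reporting the stereo-strict rate alongside —
both readings of "equality up to chirality" are available, and the
strict rate is the honest one for `sprime`. On the packaged fixture
sets both `m` and `s` recover 100% of molecules (stripped *and*
strict); the benchmark in `scripts/acceptance.py` asserts ≥ 99.9% on
1000 molecules. Molecules failing verification are reported as data
(with reasons) so corpus builders can drop them.

## Corpus and vocabulary

A sentence is `[constraint labels] [motif-info] <bos> motifs <eos>`.
Default constraint thresholds — half-open `[lo, hi)` ranges, declared
in config rather than code: QED good ≥ 0.5, logP good ∈ [0, 5),
SAS good < 4. The binary activity label uses a model-score cut of
44.36, strictly above = active. The motif-info token is the total
attachment-marker count of the sentence, exact for 0–12 and bucketed as
`13+` beyond, keeping the vocabulary bounded. Tokens are whole motif
SMILES (one token per motif); vocabulary IDs are assigned by frequency
then lexicographically after the four specials, so the same corpus
always yields the same mapping.

## Model and training

Decoder-only transformer: embeddings + sinusoidal positional encoding;
per block, masked multi-head scaled dot-product self-attention and a
ReLU two-layer FFN, each with residual connection followed by layer
normalization (post-LN); linear + softmax head. Defaults (all
configurable): d_model 256, 8 heads, 4 layers, d_ff 1024, dropout 0.1,
T = 64. Implemented in NumPy (float64) with hand-derived gradients,
verified against central finite differences in the test suite, and
Adam (β = 0.9/0.999, linear warmup, default peak 1e-3). The loss is the
next-token NLL restricted to positions after `<bos>`; constraint and
info positions are context only. Training is deterministic given
(corpus, config, seed). The tests and examples use reduced
configurations (d_model 16–64, 1–4 layers, corpora of 3–400 sentences),
which this implementation trains in seconds to tens of seconds on one
CPU core; the architecture is the same at every scale.

## Sampling

Beam search scores hypotheses by pure accumulated log-probability (no
length normalization), moves hypotheses to the finished pool on
`<eos>`, stops at the step budget T (unfinished survivors are returned
flagged), and breaks ties lexicographically by token ID, so decoding is
fully deterministic. `<pad>`/`<bos>`/`<unk>` are always banned; callers
may ban further tokens or suppress repeats. With beam width 1 this is
exactly greedy decoding, and with a beam covering the whole search tree
it provably equals exhaustive argmax (asserted in the tests). Bulk
sampling (`sample_molecules`) cycles over motif-info tokens and draws
from a temperature-reshaped distribution over the top-K continuations —
how one trained model should emit thousands of distinct molecules is
genuinely open; this declared scheme keeps per-sample determinism under
a seed while varying output.

## Fixtures

The fixture generator assembles molecules from ~30 embedded NP-common
ring systems (decalin, chromone, indole, glucopyranose, a steroid
tetracycle, bridged and spiro cores, …) joined by single bonds and
decorated with typical substituents (prenyl, acetoxy, methoxy, halogen,
…); a configurable fraction receives a randomly chosen stereoisomer.
Defaults: 1000 molecules, ≤ 3 ring systems, ≤ 4 substituents, stereo
fraction 0.3, seed 42 — sized so every cutting rule fires and fused,
isolated, bridged and acyclic cases all occur. The two-class toy corpus
(~200 sentences per class) draws class A from carbocycles + alkyl
substituents and class B from heterocycles + O/N substituents, so the
motif pools are disjoint by construction (asserted, with offenders
dropped).

What the fixtures deliberately do not emulate: COCONUT-scale property
distributions, glycosylation patterns, reactive/exotic functional
groups, very large macrocycles. Passing the round-trip and conditioning
tests therefore demonstrates correctness of the encoding and the
conditioning machinery on structurally NP-like chemistry, not
generative quality on real NP corpora — training on such corpora is
exactly what the CLI supports, but no claim about it is baked into the
tests.

## Evaluation

Validity = valid/total sampled; uniqueness = unique canonical SMILES /
valid; novelty = valid unique ∉ train / valid unique. Distribution
metrics follow the MOSES conventions on 2048-bit Morgan radius-2
fingerprints: SNN (mean nearest-neighbour Tanimoto to the reference),
internal diversity (1 − mean pairwise Tanimoto; defined as 0 for a
single molecule), and cosine similarity of BRICS-fragment and
Bemis–Murcko-scaffold count vectors. Ring systems are fused-ring
connected components (an excised aromatic ring that no longer
kekulizes standalone falls back to its fragment SMILES as the
comparison key); functional groups use the Ertl algorithm (`ifg`
module shipped with RDKit). Coverage is the fraction of generated-set
RS/FG *occurrences* present in the training set; recovery the fraction
of the generated set's *unique* RS/FGs present in the training set;
because both denominators reference the generated set, the alternative
`train_recovery` (share of the training set's unique RS/FGs that the
sample reproduces) is reported under that explicit label. Enrichment
factor: EF[X] = hit rate in the top ⌈X·n⌉ of the score-ranked list
divided by the overall hit rate; EF[1.0] ≡ 1. FCD is reported as
`null`: it requires pretrained ChemNet weights, an external download
this package deliberately avoids.

## Known limitations

* Ring opening/closing and bridged-ring recombination are not modelled;
  bridged and spiro systems travel as single motifs.
* `sprime` drops ring-fusion stereochemistry (see above).
* Double-bond (E/Z) direction markers adjacent to a cut bond may be
  lost; they sit on the cut single bond itself, which no longer exists
  in either fragment. This only affects the stereo-strict rate.
* The NumPy transformer targets desk-scale corpora; training on
  hundreds of thousands of molecules would want a GPU framework behind
  the same interfaces.
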