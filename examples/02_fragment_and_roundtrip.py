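"""Cut molecules into motifs and reconstruct them exactly.

Shows the two bond-breaking schemes (motif rules vs scaffold rules, plus
the fused-edge variant) on a steroid ester, then verifies the lossless
round trip over a 200-molecule generated NP-like set.
"""

from nimo.fixtures import FixtureSpec, generate_fixture_set
from nimo.fragmenter import fragment
from nimo.sequence import canonicalize, reconstruct, verify_roundtrip

steroid = "CC(=O)Oc1ccc2c(c1)CC[C@@H]1[C@@H]2CC[C@]2(C)[C@@H](O)CC[C@@H]12"

for mode in ("m", "s", "sprime"):
    seq = canonicalize(fragment(steroid, mode))
    print(f"\nmode {mode}: {len(seq)} motifs")
    for t in seq.tokens:
        print("  ", t)
    print("  reconstructs ->", reconstruct(seq))
# [*:n] marks an attachment point; its number is positional (1 = the
# bond back to the already-built part), so the sequence alone rebuilds
# the molecule.

mols = generate_fixture_set(FixtureSpec(n_molecules=200, seed=7))
for mode in ("m", "s"):
    rep = verify_roundtrip(mols, mode)
    print(f"\nround trip, mode {mode}: {rep['accuracy']:.1%} of {rep['n']} recovered "
          f"({rep['stereo_strict_accuracy']:.1%} stereo-strict)")
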