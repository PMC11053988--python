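"""Programmatic natural-product-like test molecules and toy corpora.

Real NP corpora (COCONUT-scale collections, terpenoid libraries) are too
large to ship and are not needed to exercise the machinery. This module
assembles molecules from a small embedded library of ring systems common
in natural products (decalin, chromone, indole, pyranose, a steroid
tetracycle, ...) joined by single bonds and decorated with typical
substituents, with an optional fraction carrying tetrahedral stereo-
centres. The assembly spans isolated rings, fused systems and acyclic
decorations so that every bond-breaking rule fires somewhere in a
default set. A fixed seed gives a byte-identical set.

The generator emulates corpus *structure*, not COCONUT's true property
distributions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .standardize import StandardMolecule, standardize_molecule

# ~30 ring systems recurring in natural products
DEFAULT_RING_LIBRARY = (
    "C1CCCCC1",            # cyclohexane
    "C1CCCC1",             # cyclopentane
    "C1CC2CCCCC2CC1",      # decalin-like
    "C1CCC2CCCCC2C1",      # decalin
    "c1ccccc1",            # benzene
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2occc2c1",       # benzofuran
    "c1ccc2sccc2c1",       # benzothiophene
    "c1ccoc1",             # furan
    "c1cc[nH]c1",          # pyrrole
    "c1ccncc1",            # pyridine
    "c1ccnnc1",            # pyridazine
    "c1cnc2[nH]ccc2c1",    # azaindole
    "O=c1ccoc2ccccc12",    # chromone
    "O=c1ccc2ccccc2o1",    # coumarin
    "O=C1CCCO1",           # butyrolactone
    "O=C1CCCCO1",          # valerolactone
    "C1CCOC1",             # tetrahydrofuran
    "C1CCOCC1",            # tetrahydropyran
    "OC1OCCCC1",           # pyranose-like hemiacetal
    "OCC1OC(O)C(O)C(O)C1O",  # glucopyranose
    "C1CCNC1",             # pyrrolidine
    "C1CCNCC1",            # piperidine
    "C1CNCCN1",            # piperazine
    "C1COCCN1",            # morpholine
    "C1CC2CCC1CC2",        # bicyclo[2.2.2]octane (bridged)
    "CC1(C)CCCC1",         # gem-dimethylcyclopentane (terpene-like)
    "CC1=CCCCC1",          # methylcyclohexene
    "C1CCC2(CC1)CCCCC2",   # spiro[5.5]undecane
    "CC12CCC(CC1)C2(C)C",  # pinane-like bridged core
    "C1CCC2CCC3CCCC3C2C1", # perhydro-phenanthrene (tricyclic)
    "CC12CCC3C(CCC4CCCCC43)C1CCC2",  # steroid-like tetracycle
)

DEFAULT_SUBSTITUENT_LIBRARY = (
    "C",          # methyl
    "CC",         # ethyl
    "C(C)C",      # isopropyl
    "CC=C(C)C",   # prenyl
    "O",          # hydroxyl
    "OC",         # methoxy
    "OC(C)=O",    # acetoxy
    "C(C)=O",     # acetyl
    "C=O",        # formyl
    "C(O)=O",     # carboxyl
    "N",          # amino
    "NC(C)=O",    # acetamido
    "C#N",        # nitrile
    "Cl",
    "Br",
    "C/C=C/C",    # crotyl (double-bond stereo)
)


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 1000
    ring_library: tuple = DEFAULT_RING_LIBRARY
    substituent_library: tuple = DEFAULT_SUBSTITUENT_LIBRARY
    max_rings: int = 3
    max_substituents: int = 4
    stereo_fraction: float = 0.3
    seed: int = 42


def _attachable(mol, rng, aromatic_ok=True) -> int | None:
    """Pick an atom able to accept one more single bond, or None."""
    idxs = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() in (6, 7)
        and a.GetTotalNumHs() >= 1
        and (aromatic_ok or not a.GetIsAromatic())
    ]
    if not idxs:
        return None
    return int(rng.choice(idxs))


def _join(a: Chem.Mol, b: Chem.Mol, rng) -> Chem.Mol | None:
    """Connect two pieces with a new single bond at random valid atoms."""
    ia = _attachable(a, rng)
    ib = _attachable(b, rng)
    if ia is None or ib is None:
        return None
    rw = Chem.RWMol(Chem.CombineMols(a, b))
    rw.AddBond(ia, a.GetNumAtoms() + ib, Chem.BondType.SINGLE)
    m = rw.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return m


def _assemble_one(spec: FixtureSpec, rng) -> str | None:
    n_rings = int(rng.integers(1, spec.max_rings + 1))
    rings = [
        Chem.MolFromSmiles(spec.ring_library[int(i)])
        for i in rng.integers(0, len(spec.ring_library), n_rings)
    ]
    mol = rings[0]
    for r in rings[1:]:
        nxt = _join(mol, r, rng)
        if nxt is None:
            return None
        mol = nxt
    n_subs = int(rng.integers(0, spec.max_substituents + 1))
    for i in rng.integers(0, len(spec.substituent_library), n_subs):
        sub = Chem.MolFromSmiles(spec.substituent_library[int(i)])
        nxt = _join(mol, sub, rng)
        if nxt is not None:
            mol = nxt
    if rng.random() < spec.stereo_fraction:
        mol = _pick_stereoisomer(mol, rng)
    return Chem.MolToSmiles(mol)


def _pick_stereoisomer(mol, rng) -> Chem.Mol:
    opts = StereoEnumerationOptions(maxIsomers=8, onlyUnassigned=True, unique=True)
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    if not isomers:
        return mol
    return isomers[int(rng.integers(0, len(isomers)))]


def generate_fixture_set(spec: FixtureSpec | None = None) -> list[StandardMolecule]:
    """Assemble, standardize and deduplicate an NP-like molecule set."""
    spec = spec or FixtureSpec()
    for s in spec.ring_library + spec.substituent_library:
        if Chem.MolFromSmiles(s) is None:
            raise ValueError(f"invalid_library_smiles: {s!r}")
    rng = np.random.default_rng(spec.seed)
    out: list[StandardMolecule] = []
    attempts = 0
    while len(out) < spec.n_molecules and attempts < 50 * max(spec.n_molecules, 1):
        attempts += 1
        smi = _assemble_one(spec, rng)
        if smi is None:
            continue
        try:
            out.append(standardize_molecule(smi, with_descriptors=False))
        except Exception:
            continue
    if len(out) < spec.n_molecules:
        raise RuntimeError("fixture assembly kept failing; libraries too restrictive")
    return out


# ---------------------------------------------------------------------------
# conditioned toy corpus for the class-recovery property
# ---------------------------------------------------------------------------

_CLASS_A_RINGS = ("C1CCCCC1", "C1CCCC1", "C1CCC2CCCCC2C1", "CC1(C)CCCC1")
_CLASS_A_SUBS = ("C", "CC", "C(C)C", "CC=C(C)C")
_CLASS_B_RINGS = ("c1ccncc1", "c1cc[nH]c1", "C1COCCN1", "c1ccc2occc2c1")
_CLASS_B_SUBS = ("OC", "N", "C#N", "NC(C)=O")


@dataclass
class ToyCorpus:
    """Two-class conditioned corpus with disjoint motif inventories."""

    sentences: list  # (class_label, parent_smiles, motif token tuple)
    pools: dict = field(default_factory=dict)  # label -> set of motif tokens


def generate_conditioned_toy_corpus(
    seed: int = 0, per_class: int = 200, mode: str = "m"
) -> ToyCorpus:
    """Build ~``per_class`` sentences per class from disjoint building blocks.

    Class A uses carbocycles with alkyl decoration, class B heterocycles
    with O/N decoration, so their motif token pools cannot overlap; any
    accidental overlap (none with the shipped libraries) is dropped.
    """
    from .fragmenter import fragment
    from .sequence import canonicalize, reconstruct

    rng = np.random.default_rng(seed)
    raw = {"A": [], "B": []}
    specs = {
        "A": (_CLASS_A_RINGS, _CLASS_A_SUBS),
        "B": (_CLASS_B_RINGS, _CLASS_B_SUBS),
    }
    for label, (rings, subs) in specs.items():
        spec = FixtureSpec(
            n_molecules=per_class,
            ring_library=rings,
            substituent_library=subs,
            max_rings=2,
            max_substituents=3,
            stereo_fraction=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for m in generate_fixture_set(spec):
            seq = canonicalize(fragment(m.smiles, mode))
            reconstruct(seq)  # every shipped sentence must decode
            raw[label].append((label, m.smiles, seq.tokens))
    pool_a = {t for _, _, toks in raw["A"] for t in toks}
    pool_b = {t for _, _, toks in raw["B"] for t in toks}
    overlap = pool_a & pool_b
    sentences = [
        s
        for label in ("A", "B")
        for s in raw[label]
        if not (set(s[2]) & overlap)
    ]
    return ToyCorpus(
        sentences=sentences,
        pools={"A": pool_a - overlap, "B": pool_b - overlap},
    )
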