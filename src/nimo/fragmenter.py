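"""Motif extraction: bond-breaking rules that cut a molecule into fragments.

Two schemes are implemented. The motif scheme (``fragment_nimo_m``) breaks
every acyclic single bond that joins a ring atom to an off-ring atom or to
an atom of another ring, plus every BRICS-cleavable bond. The scaffold
scheme (``fragment_nimo_s``) computes the Bemis-Murcko scaffold and breaks
every acyclic single bond between a scaffold atom and a side-chain atom;
with ``fuse_split=True`` (the S' variant) fused ring systems inside the
scaffold are additionally separated at shared edges, duplicating the two
shared atoms into both subrings.

Every cut inserts a pair of dummy atoms ("attachment markers") carrying a
shared bond ID as their isotope, so the original connectivity is fully
recorded. For a fused-edge separation the canonically-first subring keeps
the two shared atoms as real atoms (tagged as merge targets) while the
other subring carries ``[*]`` copies; reconstruction superposes the copies
onto the targets. This keeps the encoding lossless for hetero-fused ring
systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import BRICS, Descriptors

from .standardize import StandardMolecule

# atom properties used as in-memory bookkeeping on fragment mols
PROP_PARENT = "nimo_parent_idx"  # atom index in the (canonical-order) parent
PROP_TMP = "nimo_tmp_idx"  # scratch index used while splitting

MODE_M = "m"
MODE_S = "s"
MODE_S_PRIME = "sprime"

RULE_RING_OFFRING = "ring_offring"
RULE_BRICS = "brics"
RULE_SCAFFOLD = "scaffold_sidechain"
RULE_FUSED = "fused_edge"
RULE_WHOLE = "whole_molecule"


class FragmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Motif:
    """One fragment: marker-bearing SMILES plus bookkeeping fields.

    ``weight`` and ``n_heavy`` exclude the markers: dummies are removed
    (implicit hydrogens refill the open valence) before weighing.
    """

    smiles: str
    n_attach: int
    weight: float
    n_heavy: int
    origin_rule: str


@dataclass
class Connection:
    """A recorded cut joining two fragments.

    kind 'bond': one dummy/dummy pair that reconstructs to a single bond.
    kind 'merge': a fused-edge separation; ``pairs`` holds two
    (dummy_side, target_side) atom pairs, dummy side first.
    Atom references are (fragment index, atom index).
    """

    kind: str
    bond_id: int
    pairs: list  # [((fi, ai), (fj, aj)), ...]


@dataclass
class BrokenBond:
    u: int
    v: int
    bond_id: int
    bond_order: float
    rule: str


@dataclass
class FragmentationResult:
    parent_smiles: str
    mode: str
    frag_mols: list
    connections: list
    broken_bonds: list
    acyclic: bool = False
    _motifs: list = field(default=None, repr=False)

    @property
    def motifs(self) -> list[Motif]:
        if self._motifs is None:
            rules = self._marker_rules()
            self._motifs = [
                _motif_from_frag(f, rules.get(i, RULE_WHOLE))
                for i, f in enumerate(self.frag_mols)
            ]
        return self._motifs

    def _marker_rules(self) -> dict:
        by_bid = {b.bond_id: b.rule for b in self.broken_bonds}
        out = {}
        for conn in self.connections:
            rule = by_bid.get(conn.bond_id, RULE_FUSED)
            for pair in conn.pairs:
                for (fi, _ai) in pair:
                    out.setdefault(fi, rule)
        return out


def _as_mol(mol) -> tuple[Chem.Mol, str]:
    """Re-parse from canonical SMILES so atom order is the canonical one."""
    if isinstance(mol, StandardMolecule):
        mol = mol.smiles
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise FragmentationError(f"parse_failure: {mol!r}")
        mol = parsed
    smi = Chem.MolToSmiles(mol)
    m = Chem.MolFromSmiles(smi)
    if m is None:
        raise FragmentationError(f"parse_failure: {smi!r}")
    if len(Chem.GetMolFrags(m)) != 1:
        raise FragmentationError("not a single connected component")
    return m, smi


def _motif_from_frag(frag: Chem.Mol, rule: str) -> Motif:
    n_attach = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 0)
    core = Chem.RWMol(frag)
    core.BeginBatchEdit()
    for a in core.GetAtoms():
        if a.GetAtomicNum() == 0:
            core.RemoveAtom(a.GetIdx())
    core.CommitBatchEdit()
    m = core.GetMol()
    try:
        for a in m.GetAtoms():
            a.SetNoImplicit(False)
        Chem.SanitizeMol(m)
        weight = float(Descriptors.MolWt(m))
    except Exception:
        weight = float("nan")
    shown = Chem.Mol(frag)
    for a in shown.GetAtoms():
        a.SetIsotope(0)
    return Motif(
        smiles=Chem.MolToSmiles(shown),
        n_attach=n_attach,
        weight=weight,
        n_heavy=sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 0),
        origin_rule=RULE_WHOLE if n_attach == 0 else rule,
    )


def _single_frag_result(mol, smi, mode, acyclic=False) -> FragmentationResult:
    frag = Chem.Mol(mol)
    for a in frag.GetAtoms():
        a.SetIntProp(PROP_PARENT, a.GetIdx())
    return FragmentationResult(
        parent_smiles=smi, mode=mode, frag_mols=[frag],
        connections=[], broken_bonds=[], acyclic=acyclic,
    )


def _cut(mol, smi, cut_bonds, mode) -> FragmentationResult:
    """Break ``cut_bonds`` (list of (bond_idx, rule)), insert marker pairs."""
    if not cut_bonds:
        return _single_frag_result(mol, smi, mode)
    work = Chem.Mol(mol)
    for a in work.GetAtoms():
        a.SetIntProp(PROP_PARENT, a.GetIdx())
    # deterministic bond IDs: sorted by (min atom idx, max atom idx)
    keyed = []
    for bidx, rule in cut_bonds:
        b = work.GetBondWithIdx(bidx)
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        keyed.append((min(u, v), max(u, v), bidx, rule))
    keyed.sort()
    broken = []
    bond_indices, labels = [], []
    for bid, (u, v, bidx, rule) in enumerate(keyed, start=1):
        order = work.GetBondWithIdx(bidx).GetBondTypeAsDouble()
        broken.append(BrokenBond(u=u, v=v, bond_id=bid, bond_order=order, rule=rule))
        bond_indices.append(bidx)
        labels.append((bid, bid))
    cut_mol = Chem.FragmentOnBonds(work, bond_indices, dummyLabels=labels)
    frags = list(Chem.GetMolFrags(cut_mol, asMols=True, sanitizeFrags=True))
    # pair markers by their isotope (= bond ID)
    ends: dict[int, list] = {}
    for fi, f in enumerate(frags):
        for a in f.GetAtoms():
            if a.GetAtomicNum() == 0 and a.GetIsotope() > 0:
                ends.setdefault(a.GetIsotope(), []).append((fi, a.GetIdx()))
    conns = []
    for bid in sorted(ends):
        pair = ends[bid]
        if len(pair) != 2:
            raise FragmentationError(f"marker pairing broken for bond id {bid}")
        conns.append(Connection(kind="bond", bond_id=bid, pairs=[tuple(pair)]))
    return FragmentationResult(
        parent_smiles=smi, mode=mode, frag_mols=frags,
        connections=conns, broken_bonds=broken,
    )


def fragment_nimo_m(mol) -> FragmentationResult:
    """Ring/off-ring single-bond cuts plus BRICS cuts (union of bond sets)."""
    m, smi = _as_mol(mol)
    brics = {frozenset(b[0]) for b in BRICS.FindBRICSBonds(m)}
    cuts = []
    for b in m.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        key = frozenset((a1.GetIdx(), a2.GetIdx()))
        if a1.IsInRing() or a2.IsInRing():
            cuts.append((b.GetIdx(), RULE_RING_OFFRING))
        elif key in brics:
            cuts.append((b.GetIdx(), RULE_BRICS))
    return _cut(m, smi, cuts, MODE_M)


def murcko_scaffold_atoms(mol) -> set[int]:
    """Atom indices of the Bemis-Murcko scaffold (rings + linkers).

    Computed by iteratively pruning terminal atoms that are not in rings;
    exocyclic multiple-bond appendages are handled downstream (multiple
    bonds are never cut, so they stay attached to the scaffold fragment).
    """
    alive = {a.GetIdx() for a in mol.GetAtoms()}
    changed = True
    while changed:
        changed = False
        for idx in sorted(alive):
            a = mol.GetAtomWithIdx(idx)
            if a.IsInRing():
                continue
            deg = sum(1 for nb in a.GetNeighbors() if nb.GetIdx() in alive)
            if deg <= 1:
                alive.remove(idx)
                changed = True
    return alive


def fragment_nimo_s(mol, fuse_split: bool = False) -> FragmentationResult:
    """Murcko scaffold / side-chain cuts; optional fused-edge separation (S')."""
    m, smi = _as_mol(mol)
    mode = MODE_S_PRIME if fuse_split else MODE_S
    if m.GetRingInfo().NumRings() == 0:
        return _single_frag_result(m, smi, mode, acyclic=True)
    scaffold = murcko_scaffold_atoms(m)
    cuts = []
    for b in m.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if (u in scaffold) != (v in scaffold):
            cuts.append((b.GetIdx(), RULE_SCAFFOLD))
    result = _cut(m, smi, cuts, mode)
    if fuse_split:
        _split_fused_edges(result)
    return result


# ---------------------------------------------------------------------------
# fused-edge separation (NIMO-S')
# ---------------------------------------------------------------------------

def _eligible_shared_edge(mol):
    """First shared edge of a purely fused ring pair, or None.

    Eligible: the bond lies in exactly two SSSR rings, those rings share
    exactly the bond's two atoms, neither atom sits in more than two rings
    (bridged systems are left alone), and deleting the two atoms splits
    the fragment graph in exactly two components.
    """
    ri = mol.GetRingInfo()
    atom_rings = ri.AtomRings()
    for b in mol.GetBonds():
        if ri.NumBondRings(b.GetIdx()) != 2:
            continue
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        ua, va = mol.GetAtomWithIdx(u), mol.GetAtomWithIdx(v)
        if ri.NumAtomRings(u) > 2 or ri.NumAtomRings(v) > 2:
            continue
        shared = [set(r) for r in atom_rings if u in r and v in r]
        if len(shared) != 2 or len(shared[0] & shared[1]) != 2:
            continue
        comps = _components_without(mol, {u, v})
        ring_comps = [c for c in comps if any(mol.GetAtomWithIdx(i).IsInRing() for i in c)]
        if len(ring_comps) != 2:
            continue
        # ring-free branches hanging off u/v (markers, methyls, =O) stay
        # with the owner side, which keeps the real shared atoms
        extras = [c for c in comps if c not in ring_comps]
        ring_comps.sort(key=min)
        owner = set().union(ring_comps[0], *extras)
        return (u, v, [owner, ring_comps[1]])
    return None


def _components_without(mol, removed: set[int]) -> list[set[int]]:
    remaining = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in removed]
    seen, comps = set(), []
    for start in remaining:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j not in removed and j not in comp:
                    stack.append(j)
        seen |= comp
        comps.append(comp)
    return comps


def _take_side(mol, keep: set[int], edge: tuple[int, int], as_dummies: bool):
    """Copy of ``mol`` restricted to ``keep`` + the shared edge atoms.

    The shared atoms stay real in the owner side (``as_dummies=False``)
    and become ``[*]`` copies in the other; returns (side_mol,
    {orig_idx: new_idx}).
    """
    u, v = edge
    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        a.SetIntProp(PROP_TMP, a.GetIdx())
    rw.BeginBatchEdit()
    for a in rw.GetAtoms():
        if a.GetIdx() not in keep and a.GetIdx() not in (u, v):
            rw.RemoveAtom(a.GetIdx())
    rw.CommitBatchEdit()
    side = rw.GetMol()
    idx_map = {}
    for a in side.GetAtoms():
        idx_map[a.GetIntProp(PROP_TMP)] = a.GetIdx()
        a.ClearProp(PROP_TMP)
    for orig in (u, v):
        a = side.GetAtomWithIdx(idx_map[orig])
        a.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        if as_dummies:
            a.SetAtomicNum(0)
            a.SetFormalCharge(0)
            a.SetIsotope(0)
            a.SetNoImplicit(True)
            a.SetNumExplicitHs(0)
            if a.HasProp(PROP_PARENT):
                a.ClearProp(PROP_PARENT)
        else:
            a.SetNoImplicit(False)
            a.SetNumExplicitHs(0)
    try:
        side.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(side)
        Chem.Kekulize(side, clearAromaticFlags=True)
    except Exception as e:  # pragma: no cover - defensive
        raise FragmentationError(f"fused-edge side sanitization failed: {e}")
    return side, idx_map


def _split_fused_edges(result: FragmentationResult) -> None:
    """Separate fused rings at shared edges, in place, recording merges."""
    next_bid = max([b.bond_id for b in result.broken_bonds], default=0)
    next_bid = max([next_bid] + [c.bond_id for c in result.connections])
    frags = result.frag_mols
    i = 0
    while i < len(frags):
        f = frags[i]
        if f.GetRingInfo().NumRings() < 2:
            i += 1
            continue
        try:
            kek = Chem.Mol(f)
            Chem.Kekulize(kek, clearAromaticFlags=True)
        except Exception:
            i += 1
            continue
        edge = _eligible_shared_edge(kek)
        if edge is None:
            i += 1
            continue
        u, v, comps = edge
        owner, idx_owner = _take_side(kek, comps[0], (u, v), as_dummies=False)
        other, idx_other = _take_side(kek, comps[1], (u, v), as_dummies=True)
        next_bid += 1
        # remap connections referencing frag i into the two sides
        for conn in result.connections:
            conn.pairs = [
                tuple(
                    _remap_end(end, i, len(frags), idx_owner, idx_other, comps, (u, v))
                    for end in pair
                )
                for pair in conn.pairs
            ]
        frags[i] = owner
        frags.append(other)
        result.connections.append(
            Connection(
                kind="merge",
                bond_id=next_bid,
                pairs=[
                    ((len(frags) - 1, idx_other[u]), (i, idx_owner[u])),
                    ((len(frags) - 1, idx_other[v]), (i, idx_owner[v])),
                ],
            )
        )
        # re-examine frag i (it may itself still be fused)
    result._motifs = None


def _remap_end(end, fi, new_fi, idx_owner, idx_other, comps, edge):
    f, a = end
    if f != fi:
        return end
    if a in comps[0] or a in edge:
        return (fi, idx_owner[a])
    return (new_fi, idx_other[a])


# ---------------------------------------------------------------------------

def motif_statistics(results) -> dict:
    """Aggregate motif weight/size statistics over many fragmentations."""
    results = list(results)
    if not results:
        raise FragmentationError("empty_input")
    motifs = [m for r in results for m in r.motifs]
    hist: dict[int, int] = {}
    for m in motifs:
        hist[m.n_attach] = hist.get(m.n_attach, 0) + 1
    weights = [m.weight for m in motifs if m.weight == m.weight]
    return {
        "n_motifs": len(motifs),
        "mean_motif_weight": sum(weights) / len(weights),
        "mean_motif_size": sum(m.n_heavy for m in motifs) / len(motifs),
        "attach_histogram": dict(sorted(hist.items())),
    }


def fragment(mol, mode: str) -> FragmentationResult:
    """Dispatch by mode name: 'm', 's' or 'sprime'."""
    if mode == MODE_M:
        return fragment_nimo_m(mol)
    if mode == MODE_S:
        return fragment_nimo_s(mol, fuse_split=False)
    if mode == MODE_S_PRIME:
        return fragment_nimo_s(mol, fuse_split=True)
    raise ValueError(f"unknown fragmentation mode: {mode!r}")
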