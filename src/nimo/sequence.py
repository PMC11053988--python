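"""Canonical motif sequences and exact molecular reconstruction.

A fragmentation is an unordered bag of marker-bearing fragments whose
markers carry explicit pairing IDs. For training a language model we need
the opposite: a deterministic *ordered* sequence whose pairing is implied
by position alone, so the IDs can be dropped and identical fragments map
to identical vocabulary tokens.

Encoding. The fragments and their recorded cuts form a tree (every cut
severs an acyclic bond, and each fused-edge separation likewise adds one
node and one edge). The sequence is the DFS preorder of that tree rooted
at the fragment holding the parent's first canonical atom. Inside each
motif the markers are renumbered positionally with atom-map numbers:
map 1 (and 2, for a fused-edge pair) marks the connection to the already
emitted part of the tree, higher maps mark outgoing connections in the
motif's own canonical-rank order. A single-bond marker is a mapped dummy
atom; a fused-edge connection appears as a bonded pair of mapped dummies
on one side and a bonded pair of mapped *real* atoms (the merge targets)
on the other.

Decoding replays the DFS with a stack: the first motif's outgoing ports
are pushed (last first); each further motif pops one port, joins to it
through its map-1 port, and pushes its own outgoing ports. Single-bond
ports join via one new single bond (delegated to RDKit's molzip, which
preserves tetrahedral stereo); fused-edge ports merge by superposing each
dummy onto its target atom. No stored bond IDs are consulted anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .fragmenter import (
    PROP_PARENT,
    FragmentationResult,
    fragment,
)

_MOLZIP_BASE = 500  # map numbers used transiently for molzip pairing


class InvalidSequenceError(ValueError):
    """A motif sequence that does not decode to a molecule.

    ``reason``: dangling_marker | valence_violation |
    incompatible_fused_edge | bad_token
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class MotifSequence:
    """An ordered, self-describing motif token list for one molecule."""

    tokens: tuple
    mode: str = ""
    source_smiles: str | None = None

    def __len__(self):
        return len(self.tokens)


@dataclass
class _Port:
    kind: str  # 'bond' | 'merge'
    atoms: tuple  # local atom indices; merge pairs ordered
    peer: tuple | None = None  # (frag_idx, ordered peer atom tuple)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _frag_ranks(frag) -> list[int]:
    clean = Chem.Mol(frag)
    for a in clean.GetAtoms():
        a.SetIsotope(0)
        a.SetAtomMapNum(0)
    return list(Chem.CanonicalRankAtoms(clean, breakTies=True))


def _frag_ports(result: FragmentationResult) -> list[list[_Port]]:
    ports: list[list[_Port]] = [[] for _ in result.frag_mols]
    for conn in result.connections:
        if conn.kind == "bond":
            (fi, ai), (fj, aj) = conn.pairs[0]
            ports[fi].append(_Port("bond", (ai,), (fj, (aj,))))
            ports[fj].append(_Port("bond", (aj,), (fi, (ai,))))
        else:
            (d1, t1), (d2, t2) = conn.pairs
            fd, ft = d1[0], t1[0]
            ports[fd].append(_Port("merge", (d1[1], d2[1]), (ft, (t1[1], t2[1]))))
            ports[ft].append(_Port("merge", (t1[1], t2[1]), (fd, (d1[1], d2[1]))))
    return ports


def _root_index(result: FragmentationResult) -> int:
    for fi, f in enumerate(result.frag_mols):
        for a in f.GetAtoms():
            if (
                a.GetAtomicNum() > 0
                and a.HasProp(PROP_PARENT)
                and a.GetIntProp(PROP_PARENT) == 0
            ):
                return fi
    return 0


def canonicalize(result: FragmentationResult) -> MotifSequence:
    """Order fragments into the canonical, ID-free motif sequence."""
    n = len(result.frag_mols)
    ports = _frag_ports(result)
    if sum(len(p) for p in ports) != 2 * (n - 1):
        raise InvalidSequenceError("dangling_marker", "fragment graph is not a tree")
    ranks = [_frag_ranks(f) for f in result.frag_mols]
    tokens: list[str] = []
    visited: set[int] = set()

    def visit(fi: int, incoming: _Port | None):
        visited.add(fi)
        work = Chem.Mol(result.frag_mols[fi])
        for a in work.GetAtoms():
            a.SetIsotope(0)
            a.SetAtomMapNum(0)
        counter = 1
        if incoming is not None:
            for a_idx in incoming.atoms:  # order fixed by the parent's port
                work.GetAtomWithIdx(a_idx).SetAtomMapNum(counter)
                counter += 1
        out = [
            p
            for p in ports[fi]
            if incoming is None or set(p.atoms) != set(incoming.atoms)
        ]
        out.sort(key=lambda p: min(ranks[fi][a] for a in p.atoms))
        children = []
        for p in out:
            local = sorted(p.atoms, key=lambda a: ranks[fi][a])
            for a_idx in local:
                work.GetAtomWithIdx(a_idx).SetAtomMapNum(counter)
                counter += 1
            # reorder the peer's atoms to follow this port's local order
            order = [p.atoms.index(a) for a in local]
            peer_fi, peer_atoms = p.peer
            children.append((peer_fi, tuple(peer_atoms[k] for k in order)))
        tokens.append(Chem.MolToSmiles(work))
        for peer_fi, peer_atoms in children:
            if peer_fi in visited:
                raise InvalidSequenceError("dangling_marker", "cycle in fragment graph")
            incoming_port = next(
                p for p in ports[peer_fi] if set(p.atoms) == set(peer_atoms)
            )
            visit(peer_fi, _Port(incoming_port.kind, peer_atoms, None))

    visit(_root_index(result), None)
    if len(visited) != n:
        raise InvalidSequenceError("dangling_marker", "disconnected fragment graph")
    return MotifSequence(
        tokens=tuple(tokens), mode=result.mode, source_smiles=result.parent_smiles
    )


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _token_ports(mol) -> list[_Port]:
    """Recover the port list of one parsed token from its map numbers."""
    mapped = {a.GetAtomMapNum(): a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum()}
    maps = sorted(mapped)
    if maps != list(range(1, len(maps) + 1)):
        raise InvalidSequenceError("bad_token", "marker numbering is not 1..k")
    ports: list[_Port] = []
    used: set[int] = set()
    for m in maps:
        if m in used:
            continue
        idx = mapped[m]
        atom = mol.GetAtomWithIdx(idx)
        partner = None
        if m + 1 in mapped:
            nxt = mol.GetAtomWithIdx(mapped[m + 1])
            bonded = mol.GetBondBetweenAtoms(idx, mapped[m + 1]) is not None
            if bonded and (atom.GetAtomicNum() == 0) == (nxt.GetAtomicNum() == 0):
                partner = mapped[m + 1]
        if atom.GetAtomicNum() > 0 and partner is None:
            raise InvalidSequenceError("bad_token", "mapped heavy atom outside a merge pair")
        if partner is not None:
            ports.append(_Port("merge", (idx, partner)))
            used.update((m, m + 1))
        else:
            ports.append(_Port("bond", (idx,)))
            used.add(m)
    return ports


def reconstruct(seq, sanitize_output: bool = True) -> str:
    """Decode a motif sequence back into a canonical SMILES.

    Accepts a MotifSequence or a plain token iterable. Raises
    InvalidSequenceError when the sequence does not decode; such failures
    feed the validity metric during sampling.
    """
    tokens = list(seq.tokens if isinstance(seq, MotifSequence) else seq)
    if not tokens:
        raise InvalidSequenceError("dangling_marker", "empty sequence")
    mols, ports = [], []
    for t in tokens:
        m = Chem.MolFromSmiles(t)
        if m is None:
            raise InvalidSequenceError("bad_token", t)
        mols.append(m)
        ports.append(_token_ports(m))

    offsets, combined = [], None
    for m in mols:
        offsets.append(combined.GetNumAtoms() if combined is not None else 0)
        combined = m if combined is None else Chem.CombineMols(combined, m)

    def glob(fi, a):
        return offsets[fi] + a

    stack: list[tuple[str, tuple]] = []  # (kind, global atom tuple), LIFO
    joins = []  # ('bond', d1, d2) or ('merge', (dummies), (targets))
    for fi, plist in enumerate(ports):
        if fi == 0:
            incoming, outgoing = None, plist
        else:
            if not plist:
                raise InvalidSequenceError("dangling_marker", "unattachable motif")
            incoming, outgoing = plist[0], plist[1:]
            if not stack:
                raise InvalidSequenceError("dangling_marker", "no open attachment point")
            kind, atoms = stack.pop()
            if kind != incoming.kind:
                raise InvalidSequenceError("incompatible_fused_edge")
            here = tuple(glob(fi, a) for a in incoming.atoms)
            if kind == "bond":
                joins.append(("bond", atoms[0], here[0]))
            else:
                a_dummy = combined.GetAtomWithIdx(atoms[0]).GetAtomicNum() == 0
                b_dummy = combined.GetAtomWithIdx(here[0]).GetAtomicNum() == 0
                if a_dummy == b_dummy:
                    raise InvalidSequenceError("incompatible_fused_edge")
                dummies, targets = (atoms, here) if a_dummy else (here, atoms)
                joins.append(("merge", dummies, targets))
        for p in reversed(outgoing):
            stack.append((p.kind, tuple(glob(fi, a) for a in p.atoms)))
    if stack:
        raise InvalidSequenceError("dangling_marker", "unconsumed attachment points")

    rw = Chem.RWMol(combined)
    to_delete: list[int] = []
    try:
        for op in joins:
            if op[0] == "merge":
                _apply_merge(rw, op[1], op[2], to_delete)
        next_map = _MOLZIP_BASE
        for a in rw.GetAtoms():
            a.SetAtomMapNum(0)
        for op in joins:
            if op[0] == "bond":
                next_map += 1
                rw.GetAtomWithIdx(op[1]).SetAtomMapNum(next_map)
                rw.GetAtomWithIdx(op[2]).SetAtomMapNum(next_map)
        for idx in sorted(to_delete, reverse=True):
            rw.RemoveAtom(idx)
        out = rw.GetMol()
        if next_map > _MOLZIP_BASE:
            out = Chem.molzip(out)
        for a in out.GetAtoms():
            a.SetAtomMapNum(0)
        out.UpdatePropertyCache(strict=False)
        if sanitize_output:
            Chem.SanitizeMol(out)
    except InvalidSequenceError:
        raise
    except Exception as e:
        raise InvalidSequenceError("valence_violation", str(e))
    smiles = Chem.MolToSmiles(out)
    if Chem.MolFromSmiles(smiles) is None:
        raise InvalidSequenceError("valence_violation", "output does not re-parse")
    return Chem.CanonSmiles(smiles)


def _apply_merge(rw, dummies, targets, to_delete):
    """Superpose fused-edge dummy copies onto their real target atoms."""
    dset = set(dummies)
    for d, t in zip(dummies, targets):
        datom = rw.GetAtomWithIdx(d)
        if datom.GetAtomicNum() != 0:
            raise InvalidSequenceError("incompatible_fused_edge")
        for nb in list(datom.GetNeighbors()):
            j = nb.GetIdx()
            if j in dset:
                continue  # the shared edge itself already exists on the owner
            order = rw.GetBondBetweenAtoms(d, j).GetBondType()
            if rw.GetBondBetweenAtoms(t, j) is None:
                rw.AddBond(t, j, order)
        to_delete.append(d)
    for t in targets:
        a = rw.GetAtomWithIdx(t)
        a.SetNoImplicit(False)
        a.SetNumExplicitHs(0)
        a.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def strip_stereo(smiles: str) -> str:
    m = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(m)
    return Chem.MolToSmiles(m)


def roundtrip_one(smiles: str, mode: str) -> tuple[bool, bool, str]:
    """(matches stereo-stripped, matches stereo-strict, reason) for one molecule."""
    try:
        seq = canonicalize(fragment(smiles, mode))
        back = reconstruct(seq)
    except (InvalidSequenceError, ValueError) as e:
        return False, False, getattr(e, "reason", str(e))
    ref = Chem.CanonSmiles(smiles)
    strict = back == ref
    loose = strict or strip_stereo(back) == strip_stereo(ref)
    return loose, strict, "" if loose else "mismatch"


def verify_roundtrip(mols, mode: str) -> dict:
    """Fragment -> canonicalize -> reconstruct over a corpus.

    Accuracy compares canonical SMILES with stereochemistry stripped;
    the stereo-strict rate is reported alongside. Failures are data: they
    are returned, with reasons, so callers can drop those molecules from
    a training corpus.
    """
    smiles = [m.smiles if hasattr(m, "smiles") else str(m) for m in mols]
    n_ok = n_strict = 0
    failures = []
    for s in smiles:
        ok, strict, reason = roundtrip_one(s, mode)
        n_ok += ok
        n_strict += strict
        if not ok:
            failures.append((s, reason))
    n = len(smiles)
    return {
        "n": n,
        "accuracy": n_ok / n if n else 1.0,
        "stereo_strict_accuracy": n_strict / n if n else 1.0,
        "failures": failures,
    }
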