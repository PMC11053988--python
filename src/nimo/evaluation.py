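"""Benchmark metrics for generated molecule sets.

Covers three families: conditional metrics (validity / uniqueness /
novelty of a sample against its training set), MOSES-style distribution
metrics (nearest-neighbour similarity, BRICS-fragment and Bemis-Murcko
scaffold cosine similarities, internal diversity, all on 2048-bit Morgan
radius-2 fingerprints), structural vocabulary metrics (ring-system and
functional-group coverage/recovery), and the enrichment factor of a
score-ranked screen.

FCD is deliberately not computed: it needs pretrained ChemNet weights,
an external download; the report carries ``fcd: None``.
"""

from __future__ import annotations

import math
import os
import sys
from collections import Counter

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import BRICS, RDConfig, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

sys.path.append(os.path.join(RDConfig.RDContribDir, "IFG"))
import ifg  # noqa: E402  (Ertl functional-group algorithm, ships with RDKit)

RDLogger.DisableLog("rdApp.*")


class EvaluationError(ValueError):
    pass


_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _mols(smiles_list):
    out = []
    for s in smiles_list:
        m = Chem.MolFromSmiles(s)
        if m is not None:
            out.append(m)
    return out


def _fps(mols):
    return [_fpgen.GetFingerprint(m) for m in mols]


# ---------------------------------------------------------------------------
# conditional metrics
# ---------------------------------------------------------------------------

def conditional_metrics(generated, train_set) -> dict:
    """Validity, uniqueness and novelty of a generated sample.

    ``generated``: iterables of dicts with ``smiles``/``valid`` (as
    produced by sampling) or plain SMILES/None entries. ``train_set``:
    training canonical SMILES. uniqueness is unique/valid; novelty is
    (valid unique not in train)/(valid unique).
    """
    generated = list(generated)
    if not generated:
        raise EvaluationError("empty_generated")
    smiles = []
    for g in generated:
        if isinstance(g, dict):
            smiles.append(g["smiles"] if g.get("valid") else None)
        else:
            smiles.append(g)
    valid = []
    for s in smiles:
        if s is None:
            continue
        m = Chem.MolFromSmiles(s)
        if m is not None:
            valid.append(Chem.MolToSmiles(m))
    train = {Chem.CanonSmiles(s) for s in train_set}
    unique = set(valid)
    novel = unique - train
    return {
        "validity": len(valid) / len(generated),
        "uniqueness": len(unique) / len(valid) if valid else 0.0,
        "novelty": len(novel) / len(unique) if unique else 0.0,
    }


# ---------------------------------------------------------------------------
# distribution metrics
# ---------------------------------------------------------------------------

def _count_cosine(c1: Counter, c2: Counter) -> float:
    keys = set(c1) | set(c2)
    if not keys:
        return 1.0
    v1 = np.array([c1.get(k, 0) for k in keys], dtype=float)
    v2 = np.array([c2.get(k, 0) for k in keys], dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    return float(v1 @ v2 / (n1 * n2))


def _brics_counter(mols) -> Counter:
    c: Counter = Counter()
    for m in mols:
        c.update(BRICS.BRICSDecompose(m))
    return c


def _scaffold_counter(mols) -> Counter:
    c: Counter = Counter()
    for m in mols:
        c[MurckoScaffold.MurckoScaffoldSmiles(mol=m)] += 1
    return c


def distribution_metrics(generated, reference) -> dict:
    """SNN, fragment/scaffold cosine similarity and internal diversity.

    SNN: mean over generated molecules of the maximum Tanimoto to the
    reference set. IntDiv: 1 - mean pairwise Tanimoto within the
    generated set (0 for a single molecule).
    """
    gen = _mols(generated)
    ref = _mols(reference)
    if not gen or not ref:
        raise EvaluationError("empty_set")
    gfps, rfps = _fps(gen), _fps(ref)
    snn = float(
        np.mean([max(DataStructs.BulkTanimotoSimilarity(f, rfps)) for f in gfps])
    )
    if len(gfps) < 2:
        intdiv = 0.0
    else:
        sims = [
            s
            for i, f in enumerate(gfps[:-1])
            for s in DataStructs.BulkTanimotoSimilarity(f, gfps[i + 1:])
        ]
        intdiv = float(1.0 - np.mean(sims))
    return {
        "snn": snn,
        "frag_sim": _count_cosine(_brics_counter(gen), _brics_counter(ref)),
        "scaf_sim": _count_cosine(_scaffold_counter(gen), _scaffold_counter(ref)),
        "intdiv": intdiv,
    }


# ---------------------------------------------------------------------------
# ring systems and functional groups
# ---------------------------------------------------------------------------

def ring_systems(mol) -> list[str]:
    """Canonical SMILES of each fused-ring connected component."""
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()]
    if not rings:
        return []
    merged: list[set] = []
    for r in rings:
        grew = r
        rest = []
        for m in merged:
            if m & grew:
                grew = grew | m
            else:
                rest.append(m)
        merged = rest + [grew]
    # merge transitively until stable
    stable = False
    while not stable:
        stable = True
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if merged[i] & merged[j]:
                    merged[i] |= merged.pop(j)
                    stable = False
                    break
            if not stable:
                break
    out = []
    for atoms in merged:
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
        ]
        smi = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), bondsToUse=bonds)
        # an excised aromatic ring may not kekulize on its own (e.g. a
        # pyridinone ring without its exocyclic oxygen); fall back to the
        # fragment SMILES, which is still canonical for comparison purposes
        frag = Chem.MolFromSmiles(smi)
        out.append(Chem.MolToSmiles(frag) if frag is not None else smi)
    return out


def functional_groups(mol) -> list[str]:
    """Ertl-algorithm functional group types (atoms + environment)."""
    return [g.type for g in ifg.identify_functional_groups(mol)]


def _coverage_recovery(gen_items: list[str], train_items: list[str]) -> dict:
    """Occurrence coverage and unique recovery of structural features.

    coverage: fraction of generated-set occurrences whose feature also
    exists in the training set; recovery: fraction of the generated
    set's unique features existing in the training set. train_recovery
    (fraction of the training set's unique features that the generated
    set reproduces) is reported as a labelled alternative.
    """
    train_unique = set(train_items)
    gen_unique = set(gen_items)
    n_occ = len(gen_items)
    hits_occ = sum(1 for x in gen_items if x in train_unique)
    hits_unique = len(gen_unique & train_unique)
    return {
        "coverage": hits_occ / n_occ if n_occ else 0.0,
        "recovery": hits_unique / len(gen_unique) if gen_unique else 0.0,
        "train_recovery": hits_unique / len(train_unique) if train_unique else 0.0,
    }


def rs_fg_metrics(generated, train) -> dict:
    """Ring-system and functional-group coverage/recovery."""
    gen = _mols(generated)
    tr = _mols(train)
    if not gen or not tr:
        raise EvaluationError("empty_set")
    gen_rs = [r for m in gen for r in ring_systems(m)]
    tr_rs = [r for m in tr for r in ring_systems(m)]
    gen_fg = [g for m in gen for g in functional_groups(m)]
    tr_fg = [g for m in tr for g in functional_groups(m)]
    return {
        "ring_systems": _coverage_recovery(gen_rs, tr_rs),
        "functional_groups": _coverage_recovery(gen_fg, tr_fg),
    }


# ---------------------------------------------------------------------------
# enrichment factor
# ---------------------------------------------------------------------------

def enrichment_factor(scores, fractions=(0.01, 0.05, 0.10, 0.50, 1.0)) -> dict:
    """EF[X] = hit rate within the top X of the ranked list / overall hit rate.

    ``scores``: (score, active flag) pairs, ranked by descending score;
    the top slice holds ceil(X*n) entries. EF[1.0] is identically 1.
    """
    scores = list(scores)
    if not scores:
        raise EvaluationError("empty_scores")
    n = len(scores)
    n_active = sum(1 for _s, a in scores if a)
    if n_active == 0:
        raise EvaluationError("no_actives")
    ranked = sorted(scores, key=lambda t: -t[0])
    base = n_active / n
    out = {}
    for x in fractions:
        top = max(1, math.ceil(x * n))
        hits = sum(1 for _s, a in ranked[:top] if a)
        out[x] = (hits / top) / base
    return out


def evaluate(generated, train, reference=None) -> dict:
    """Full report: conditional + distribution + RS/FG metrics."""
    valid = [
        g["smiles"] if isinstance(g, dict) else g
        for g in generated
        if (g.get("valid") if isinstance(g, dict) else g is not None)
    ]
    report = {"conditional": conditional_metrics(generated, train), "fcd": None}
    if valid:
        report["distribution"] = distribution_metrics(valid, reference or train)
        report.update(rs_fg_metrics(valid, train))
    return report
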