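"""Molecule standardization and descriptor computation.

Raw SMILES from natural-product collections arrive as salts, charged
species and occasional garbage. Before fragmentation every molecule is
desalted (largest organic fragment kept), neutralized where a simple
protonation/deprotonation fixes the charge, and canonicalized with
stereochemistry preserved. Seven descriptors used downstream as
conditioning constraints and evaluation axes are computed per molecule:
QED, logP, SAS (Ertl-Schuffenhauer synthetic accessibility, 1 easy to
10 hard), molecular weight, H-bond donors/acceptors and rotatable bonds.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, RDConfig
from rdkit.Chem.MolStandardize import rdMolStandardize

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (shipped with RDKit, not on the default path)

RDLogger.DisableLog("rdApp.*")

DESCRIPTOR_NAMES = ("qed", "logp", "sas", "mw", "hbd", "hba", "rb")


class StandardizationError(ValueError):
    """Raised when a raw SMILES cannot be standardized.

    ``reason`` is one of ``parse_failure`` or ``empty_after_desalt``.
    """

    def __init__(self, reason: str, raw_smiles: str = ""):
        self.reason = reason
        self.raw_smiles = raw_smiles
        super().__init__(f"{reason}: {raw_smiles!r}")


@dataclass(frozen=True)
class StandardMolecule:
    """A cleaned molecule: canonical SMILES plus its descriptor map."""

    smiles: str
    descriptors: dict = field(default_factory=dict, compare=False)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


_uncharger = rdMolStandardize.Uncharger()
_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def standardize_molecule(
    raw_smiles: str,
    keep_stereo: bool = True,
    with_descriptors: bool = True,
) -> StandardMolecule:
    """Desalt, neutralize and canonicalize one SMILES.

    Keeps the largest organic fragment, neutralizes formal charges where
    chemically possible (atoms that cannot be neutralized without a
    valence violation stay charged), and returns the canonical,
    stereochemistry-preserving SMILES. Glycoside trimming is not part of
    default standardization (see docs/methods.md).

    Raises
    ------
    StandardizationError
        ``parse_failure`` for unparseable input, ``empty_after_desalt``
        if nothing remains after fragment selection.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise StandardizationError("parse_failure", raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StandardizationError("parse_failure", raw_smiles)
    if mol.GetNumAtoms() == 0:
        raise StandardizationError("empty_after_desalt", raw_smiles)
    mol = _chooser.choose(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError("empty_after_desalt", raw_smiles)
    mol = _uncharger.uncharge(mol)
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    smiles = Chem.MolToSmiles(mol)
    # re-parse so descriptor computation sees the canonical form
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # uncharger produced something unparseable; reject
        raise StandardizationError("parse_failure", raw_smiles)
    desc = compute_descriptors(mol) if with_descriptors else {}
    return StandardMolecule(smiles=smiles, descriptors=desc)


def compute_descriptors(mol) -> dict:
    """The seven-descriptor panel: QED, logP, SAS, Mw, HBD, HBA, RB.

    Accepts a Mol, a SMILES string, or a StandardMolecule; pure function
    of the canonical SMILES.
    """
    if isinstance(mol, StandardMolecule):
        mol = mol.mol()
    elif isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    if mol is None:
        raise StandardizationError("parse_failure")
    return {
        "qed": float(QED.qed(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "sas": float(sascorer.calculateScore(mol)),
        "mw": float(Descriptors.MolWt(mol)),
        "hbd": int(Lipinski.NumHDonors(mol)),
        "hba": int(Lipinski.NumHAcceptors(mol)),
        "rb": int(Lipinski.NumRotatableBonds(mol)),
    }


def deduplicate(mols: list[StandardMolecule]) -> list[StandardMolecule]:
    """Drop repeated canonical SMILES, keeping first occurrences in order."""
    seen: set[str] = set()
    out = []
    for m in mols:
        if m.smiles not in seen:
            seen.add(m.smiles)
            out.append(m)
    return out


def standardize_many(
    raw: list[str], keep_stereo: bool = True, with_descriptors: bool = True
) -> tuple[list[StandardMolecule], list[tuple[str, str]]]:
    """Standardize a batch; returns (molecules, rejections as (smiles, reason))."""
    ok, bad = [], []
    for s in raw:
        try:
            ok.append(standardize_molecule(s, keep_stereo, with_descriptors))
        except StandardizationError as e:
            bad.append((s, e.reason))
    return ok, bad
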