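"""Standardize raw SMILES and compute the descriptor panel.

Desalts, neutralizes and canonicalizes a few raw inputs, then prints
the seven descriptors used as conditioning constraints (QED, logP, SAS)
and evaluation axes (Mw, HBD, HBA, RB).
"""

from nimo.standardize import standardize_many

raw = [
    "CC(=O)O.[Na+]",                 # sodium acetate -> acetic acid
    "C[NH3+].[Cl-]",                 # methylammonium chloride -> methylamine
    "CC(=O)Oc1ccccc1C(=O)O",         # aspirin, already clean
    "not_a_smiles",                  # rejected
]

mols, rejected = standardize_many(raw)
for m in mols:
    d = m.descriptors
    print(f"{m.smiles:28s} QED={d['qed']:.2f} logP={d['logp']:5.2f} "
          f"SAS={d['sas']:.2f} Mw={d['mw']:6.1f} HBD={d['hbd']} HBA={d['hba']} RB={d['rb']}")
for smi, reason in rejected:
    print(f"rejected ({reason}): {smi}")

# QED in [0,1] (higher = more drug-like); SAS in [1,10] (lower = easier
# to synthesize). These scalars drive the good/bad constraint labels.
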