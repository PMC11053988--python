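import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from nimo.fragmenter import (
    MODE_M,
    MODE_S,
    MODE_S_PRIME,
    fragment,
    fragment_nimo_m,
    fragment_nimo_s,
    motif_statistics,
    murcko_scaffold_atoms,
)


def heavy_atoms(smiles):
    return Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()


class TestNimoM:
    def test_methylcyclohexane_splits_ring_and_methyl(self):
        res = fragment_nimo_m("CC1CCCCC1")
        assert len(res.motifs) == 2
        sizes = sorted(m.n_heavy for m in res.motifs)
        assert sizes == [1, 6]
        assert all(m.n_attach == 1 for m in res.motifs)

    def test_benzene_whole_molecule(self):
        res = fragment_nimo_m("c1ccccc1")
        assert len(res.motifs) == 1
        assert res.motifs[0].n_attach == 0
        assert res.motifs[0].origin_rule == "whole_molecule"

    def test_bicyclohexyl_ring_ring_bond_cut(self):
        res = fragment_nimo_m("C1CCC(CC1)C1CCCCC1")
        assert len(res.motifs) == 2
        assert [m.n_heavy for m in res.motifs] == [6, 6]
        assert all(m.n_attach == 1 for m in res.motifs)

    def test_never_breaks_ring_bonds(self, fixture_set_small):
        for m in fixture_set_small:
            mol = Chem.MolFromSmiles(m.smiles)
            res = fragment_nimo_m(m.smiles)
            for bb in res.broken_bonds:
                assert not mol.GetBondBetweenAtoms(bb.u, bb.v).IsInRing()


class TestNimoS:
    def test_ethylbenzene_scaffold_and_sidechain(self):
        res = fragment_nimo_s("CCc1ccccc1")
        smis = sorted((m.n_heavy, m.n_attach) for m in res.motifs)
        assert smis == [(2, 1), (6, 1)]

    def test_plain_ring_is_whole_molecule(self):
        res = fragment_nimo_s("C1CCCCC1")
        assert len(res.motifs) == 1 and res.motifs[0].n_attach == 0

    def test_acyclic_molecule_flagged_whole(self):
        res = fragment_nimo_s("CCCC")
        assert res.acyclic
        assert len(res.motifs) == 1

    def test_scaffold_atoms_of_acetophenone_is_ring(self):
        mol = Chem.MolFromSmiles("CC(=O)c1ccccc1")
        atoms = murcko_scaffold_atoms(mol)
        assert atoms == {a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()}

    def test_exocyclic_carbonyl_stays_with_scaffold(self):
        # cyclohexanone: the double-bonded O is never cut away
        res = fragment_nimo_s("O=C1CCCCC1")
        assert len(res.motifs) == 1


class TestNimoSPrime:
    def test_decalin_separates_into_two_rings(self):
        res = fragment_nimo_s("C1CCC2CCCCC2C1", fuse_split=True)
        assert len(res.motifs) == 2
        merge = [c for c in res.connections if c.kind == "merge"]
        assert len(merge) == 1 and len(merge[0].pairs) == 2

    def test_shared_edge_copies_are_bonded_dummy_pair_in_a_ring(self):
        res = fragment_nimo_s("C1CCC2CCCCC2C1", fuse_split=True)
        dummy_frags = [
            f for f in res.frag_mols
            if any(a.GetAtomicNum() == 0 for a in f.GetAtoms())
        ]
        assert len(dummy_frags) == 1
        f = dummy_frags[0]
        dummies = [a for a in f.GetAtoms() if a.GetAtomicNum() == 0]
        assert len(dummies) == 2
        bond = f.GetBondBetweenAtoms(dummies[0].GetIdx(), dummies[1].GetIdx())
        assert bond is not None and bond.IsInRing()

    def test_bridged_ring_left_alone(self):
        # bicyclo[2.2.2]octane has no purely fused shared edge
        res = fragment_nimo_s("C1CC2CCC1CC2", fuse_split=True)
        assert len(res.motifs) == 1

    def test_steroid_tetracycle_splits_into_four_rings(self):
        res = fragment_nimo_s("CC12CCC3C(CCC4CCCCC43)C1CCC2", fuse_split=True)
        ring_motifs = [m for m in res.motifs if m.n_heavy >= 4]
        assert len([c for c in res.connections if c.kind == "merge"]) == 3
        assert len(res.motifs) >= 4
        assert len(ring_motifs) >= 4


class TestInvariants:
    @pytest.mark.parametrize("mode", [MODE_M, MODE_S, MODE_S_PRIME])
    def test_heavy_atom_conservation(self, fixture_set_small, mode):
        for m in fixture_set_small:
            res = fragment(m.smiles, mode)
            total = sum(mt.n_heavy for mt in res.motifs)
            assert total == heavy_atoms(m.smiles)

    @pytest.mark.parametrize("mode", [MODE_M, MODE_S, MODE_S_PRIME])
    def test_marker_pairing(self, fixture_set_small, mode):
        for m in fixture_set_small:
            res = fragment(m.smiles, mode)
            for conn in res.connections:
                if conn.kind == "bond":
                    assert len(conn.pairs) == 1
                else:
                    assert len(conn.pairs) == 2
            # total markers = dummies; each bond conn uses 2, each merge 2
            n_dummies = sum(
                1 for f in res.frag_mols for a in f.GetAtoms() if a.GetAtomicNum() == 0
            )
            expected = sum(
                2 if c.kind in ("bond", "merge") else 0 for c in res.connections
            )
            assert n_dummies == expected

    def test_mean_motif_weight_below_parent_weight(self, fixture_set_small):
        results = [fragment_nimo_m(m.smiles) for m in fixture_set_small]
        stats = motif_statistics(results)
        parent_mean = sum(
            Descriptors.MolWt(Chem.MolFromSmiles(m.smiles)) for m in fixture_set_small
        ) / len(fixture_set_small)
        assert stats["mean_motif_weight"] < parent_mean

    def test_motif_statistics_arithmetic(self):
        res = [fragment_nimo_m("CC1CCCCC1")]  # motifs of 1 and 6 heavy atoms
        stats = motif_statistics(res)
        assert stats["mean_motif_size"] == pytest.approx(3.5)
        assert sum(stats["attach_histogram"].values()) == stats["n_motifs"] == 2

    def test_motif_statistics_empty_input(self):
        with pytest.raises(ValueError):
            motif_statistics([])
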