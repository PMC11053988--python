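import pytest
from rdkit import Chem

from nimo.evaluation import (
    EvaluationError,
    conditional_metrics,
    distribution_metrics,
    enrichment_factor,
    functional_groups,
    ring_systems,
    rs_fg_metrics,
)


class TestConditionalMetrics:
    def test_hand_counts_on_ten_items(self):
        gen = ["CCO", "CCN", "CCO", "c1ccccc1", None, None,
               "CC(=O)O", "CCCC", "CCC", "CO"]
        train = ["CCO", "CCCC"]
        m = conditional_metrics(gen, train)
        assert m["validity"] == pytest.approx(0.8)  # 8 valid of 10
        assert m["uniqueness"] == pytest.approx(7 / 8)  # CCO repeated
        assert m["novelty"] == pytest.approx(5 / 7)  # CCO, CCCC seen in train

    def test_all_in_train_gives_zero_novelty(self):
        m = conditional_metrics(["CCO", "OCC"], ["CCO"])
        assert m["novelty"] == 0.0

    def test_all_distinct_valid(self):
        m = conditional_metrics(["CCO", "CCN", "CCC"], ["C"])
        assert m["uniqueness"] == 1.0 and m["validity"] == 1.0

    def test_dict_records_with_valid_flags(self):
        gen = [{"smiles": "CCO", "valid": True}, {"smiles": None, "valid": False}]
        assert conditional_metrics(gen, ["C"])["validity"] == 0.5

    def test_empty_generated(self):
        with pytest.raises(EvaluationError):
            conditional_metrics([], ["C"])


class TestDistributionMetrics:
    SET = ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1"]

    def test_self_comparison_identities(self):
        m = distribution_metrics(self.SET, self.SET)
        assert m["snn"] == pytest.approx(1.0)
        assert m["frag_sim"] == pytest.approx(1.0)
        assert m["scaf_sim"] == pytest.approx(1.0)

    def test_single_molecule_intdiv_is_zero(self):
        assert distribution_metrics(["CCO"], ["CCO"])["intdiv"] == 0.0

    def test_permutation_invariance(self):
        a = distribution_metrics(self.SET, self.SET[::-1])
        b = distribution_metrics(self.SET[::-1], self.SET)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_empty_raises(self):
        with pytest.raises(EvaluationError):
            distribution_metrics([], self.SET)


class TestRingSystemsAndFGs:
    def test_fused_ring_components_hand_enumeration(self):
        mol = Chem.MolFromSmiles("c1ccc2ccccc2c1CC1CCCCC1")
        rs = sorted(ring_systems(mol))
        assert rs == ["C1CCCCC1", "c1ccc2ccccc2c1"]

    def test_acyclic_has_no_ring_systems(self):
        assert ring_systems(Chem.MolFromSmiles("CCO")) == []

    def test_ertl_fg_detects_ester(self):
        fgs = functional_groups(Chem.MolFromSmiles("CC(=O)OC"))
        assert fgs  # ester carbonyl environment found

    def test_recovery_one_when_generated_subset_of_train(self):
        gen = ["CC1CCCCC1", "CCc1ccccc1O"]
        train = gen + ["C1CCNCC1"]
        m = rs_fg_metrics(gen, train)
        assert m["ring_systems"]["recovery"] == 1.0
        assert m["ring_systems"]["coverage"] == 1.0

    def test_coverage_zero_when_disjoint(self):
        m = rs_fg_metrics(["C1CCCCC1"], ["c1ccncc1"])
        assert m["ring_systems"]["coverage"] == 0.0

    def test_five_molecule_hand_counts(self):
        gen = ["C1CCCCC1C", "c1ccccc1", "C1CCCCC1O", "CCCC", "c1ccc2ccccc2c1"]
        train = ["C1CCCCC1", "CC(C)c1ccccc1"]
        m = rs_fg_metrics(gen, train)["ring_systems"]
        # occurrences: cyclohexane x2, benzene x1, naphthalene x1 -> 3/4 hit
        assert m["coverage"] == pytest.approx(3 / 4)
        # unique: {cyclohexane, benzene, naphthalene} -> 2/3 in train
        assert m["recovery"] == pytest.approx(2 / 3)
        assert m["train_recovery"] == pytest.approx(1.0)


class TestEnrichmentFactor:
    def test_all_actives_first(self):
        scores = [(10 - i, i == 0) for i in range(10)]  # 1 active of 10, ranked top
        ef = enrichment_factor(scores, [0.1, 1.0])
        assert ef[0.1] == pytest.approx(10.0)
        assert ef[1.0] == pytest.approx(1.0)

    def test_uniform_actives_near_one(self):
        scores = [(100 - i, i % 10 == 0) for i in range(100)]
        ef = enrichment_factor(scores, [0.1, 0.5, 1.0])
        for x, v in ef.items():
            assert v == pytest.approx(1.0, abs=0.35)

    def test_ef_bounded_by_inverse_base_rate(self):
        scores = [(10 - i, i < 2) for i in range(10)]  # base rate 0.2
        ef = enrichment_factor(scores, [0.2, 0.5, 1.0])
        assert all(v <= 1 / 0.2 + 1e-9 for v in ef.values())

    def test_error_cases(self):
        with pytest.raises(EvaluationError):
            enrichment_factor([])
        with pytest.raises(EvaluationError):
            enrichment_factor([(1.0, False)])
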