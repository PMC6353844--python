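"""Strict/soft node variants, precedence and cohort personalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logiprofile.fixtures import (
    fixture_knowledge_base,
    mini_cancer_model,
    mini_model_mapping,
)
from logiprofile.genomics import (
    CnaRecord,
    MutationRecord,
    build_discrete_profile,
)
from logiprofile.model import write_bnd
from logiprofile.personalize import (
    STRATEGIES,
    CohortData,
    GeneNodeMapping,
    PatientProfile,
    PersonalizationStrategy,
    apply_profile,
    apply_soft_nv,
    apply_strict_nv,
    build_patient_profile,
    map_genes_to_nodes,
    personalize_cohort,
    resolve_precedence,
)


class TestStrictNodeVariants:
    def test_freeze_off_zeroes_up_rate(self, mini):
        model, base = mini
        new = apply_strict_nv(base, "p53", 0)
        ns = new.node_settings["p53"]
        assert (ns.initial_prob, ns.k_up) == (0.0, 0.0)
        assert ns.k_down == base.node_settings["p53"].k_down  # untouched

    def test_freeze_on_zeroes_down_rate(self, mini):
        model, base = mini
        ns = apply_strict_nv(base, "AKT", 1).node_settings["AKT"]
        assert (ns.initial_prob, ns.k_down) == (1.0, 0.0)

    def test_base_settings_not_mutated(self, mini):
        model, base = mini
        apply_strict_nv(base, "p53", 0)
        assert base.node_settings["p53"].k_up == 1.0
        assert base.node_settings["p53"].initial_prob == 0.5

    def test_invalid_inputs_rejected(self, mini):
        model, base = mini
        with pytest.raises(ValueError):
            apply_strict_nv(base, "p53", 2)
        with pytest.raises(KeyError):
            apply_strict_nv(base, "NOPE", 1)


class TestSoftNodeVariants:
    def test_worked_rate_values(self, mini):
        """norm = 0.8, AF = 100 → k_up = 100^0.6 ≈ 15.8489, k_down = 1/k_up."""
        model, base = mini
        ns = apply_soft_nv(base, "AKT", 0.8).node_settings["AKT"]
        assert ns.initial_prob == 0.8
        assert ns.k_up == pytest.approx(100.0 ** 0.6)
        assert ns.k_up == pytest.approx(15.848931924611133)
        assert ns.k_down == pytest.approx(1.0 / ns.k_up)

    def test_extremes_and_midpoint(self, mini):
        model, base = mini
        top = apply_soft_nv(base, "AKT", 1.0).node_settings["AKT"]
        assert (top.k_up, top.k_down) == (100.0, 0.01)
        bottom = apply_soft_nv(base, "AKT", 0.0).node_settings["AKT"]
        assert (bottom.k_up, bottom.k_down) == (0.01, 100.0)
        mid = apply_soft_nv(base, "AKT", 0.5).node_settings["AKT"]
        assert (mid.k_up, mid.k_down) == (1.0, 1.0)

    def test_out_of_range_rejected(self, mini):
        model, base = mini
        with pytest.raises(ValueError):
            apply_soft_nv(base, "AKT", 1.2)
        with pytest.raises(ValueError):
            apply_soft_nv(base, "AKT", 0.5, amplification_factor=1.0)


@settings(derandomize=True, max_examples=60)
@given(norm=st.floats(0.0, 1.0), af=st.floats(1.5, 1e4))
def test_soft_rates_reciprocal_and_symmetric(norm, af):
    """k_up · k_down = 1 always, and replacing norm by 1 − norm swaps the
    two rates."""
    model, base = mini_cancer_model()
    a = apply_soft_nv(base, "AKT", norm, af).node_settings["AKT"]
    b = apply_soft_nv(base, "AKT", 1.0 - norm, af).node_settings["AKT"]
    assert a.k_up * a.k_down == pytest.approx(1.0, rel=1e-9)
    assert a.k_up == pytest.approx(b.k_down, rel=1e-9)


class TestGeneFamilyAggregation:
    def test_continuous_family_mean(self):
        mapping = mini_model_mapping()
        vals = map_genes_to_nodes({"AKT1": 0.8, "AKT2": 0.4}, mapping)
        assert vals["AKT"] == pytest.approx(0.6)

    def test_continuous_partial_family_uses_present_genes(self):
        mapping = mini_model_mapping()
        vals = map_genes_to_nodes({"AKT1": 0.8}, mapping)
        assert vals["AKT"] == pytest.approx(0.8)

    def test_discrete_unanimous_family_propagates(self):
        mapping = mini_model_mapping()
        vals = map_genes_to_nodes({"AKT1": 1.0, "AKT2": 1.0}, mapping,
                                  kind="discrete")
        assert vals["AKT"] == 1.0

    def test_discrete_conflicting_family_drops_node(self, caplog):
        mapping = mini_model_mapping()
        with caplog.at_level("WARNING", logger="logiprofile.personalize"):
            vals = map_genes_to_nodes({"AKT1": 1.0, "AKT2": 0.0}, mapping,
                                      kind="discrete")
        assert "AKT" not in vals
        assert "conflicting" in caplog.text

    def test_nan_values_treated_as_missing(self):
        mapping = mini_model_mapping()
        vals = map_genes_to_nodes({"AKT1": float("nan"), "AKT2": 0.4}, mapping)
        assert vals["AKT"] == pytest.approx(0.4)


class TestPrecedence:
    def test_mutation_beats_cna_beats_binarized_rna(self):
        prof = resolve_precedence(
            "P1",
            {"p53": [(1, "rna_binarized"), (0, "mutation"), (1, "cna")]},
            {},
            STRATEGIES["case2"],
        )
        assert prof.strict["p53"] == (0, "mutation")

    def test_strict_silences_soft_for_same_node(self):
        prof = resolve_precedence(
            "P1",
            {"p53": [(0, "mutation")]},
            {"p53": [(0.9, "rna")], "AKT": [(0.3, "rna")]},
            STRATEGIES["case5"],
        )
        assert prof.strict["p53"] == (0, "mutation")
        assert "p53" not in prof.soft
        assert prof.soft["AKT"] == (0.3, "rna")

    def test_protein_beats_rna_beats_cna_softly(self):
        strategy = PersonalizationStrategy("x", (), ("protein", "rna", "cna"))
        prof = resolve_precedence(
            "P1",
            {},
            {"AKT": [(0.2, "cna"), (0.9, "protein"), (0.5, "rna")]},
            strategy,
        )
        assert prof.soft["AKT"] == (0.9, "protein")

    def test_profile_rejects_node_in_both_channels(self):
        with pytest.raises(ValueError, match="both"):
            PatientProfile("P1", strict={"A": (1, "mutation")},
                           soft={"A": (0.5, "rna")})


class TestStrategyRecipes:
    def test_the_six_standard_recipes(self):
        expect = {
            "case1": (("mutation",), ()),
            "case2": (("mutation", "cna"), ()),
            "case3": (("mutation",), ("cna",)),
            "case4": ((), ("rna",)),
            "case5": (("mutation",), ("rna",)),
            "case6": (("mutation", "cna"), ("rna",)),
        }
        assert set(STRATEGIES) == set(expect)
        for name, (strict, soft) in expect.items():
            s = STRATEGIES[name]
            assert (s.strict_sources, s.soft_sources) == (strict, soft)
            assert s.amplification_factor == 100.0

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            PersonalizationStrategy("bad", ("methylation",), ())


def _cohort_data():
    kb = fixture_knowledge_base()
    muts = [
        MutationRecord("P1", "TP53", "nonsense"),
        MutationRecord("P2", "PIK3CA", "missense", "p.H1047R",
                       sift_label="deleterious"),
    ]
    cnas = [CnaRecord("P1", "CCND1", 2), CnaRecord("P3", "EGFR", -2)]
    mut_prof = build_discrete_profile(muts, [], kb)
    cna_prof = build_discrete_profile([], cnas, kb)
    rna = pd.DataFrame(
        {
            "P1": {"AKT1": 0.9, "AKT2": 0.7, "TP53": 0.2},
            "P2": {"AKT1": 0.1, "AKT2": 0.3, "TP53": 0.6},
        }
    )
    return CohortData(
        mutations=mut_prof,
        cna=cna_prof,
        rna=rna,
        mutation_samples=["P1", "P2", "P3"],
        cna_samples=["P1", "P2", "P3"],
    )


class TestCohortPersonalization:
    def test_case5_profile_contents(self, mini):
        model, base = mini
        data = _cohort_data()
        prof = build_patient_profile("P1", data, mini_model_mapping(),
                                     STRATEGIES["case5"])
        assert prof.strict == {"p53": (0, "mutation")}
        assert prof.soft["AKT"] == (pytest.approx(0.8), "rna")
        assert "p53" not in prof.soft  # strict silences the RNA value

    def test_apply_profile_combines_both_channels(self, mini):
        model, base = mini
        data = _cohort_data()
        prof = build_patient_profile("P1", data, mini_model_mapping(),
                                     STRATEGIES["case5"])
        s = apply_profile(base, prof)
        assert s.node_settings["p53"].k_up == 0.0
        assert s.node_settings["AKT"].k_up == pytest.approx(100.0 ** 0.6)
        # untouched nodes keep generic settings
        assert s.node_settings["RTK"].k_up == 1.0

    def test_patients_missing_required_data_excluded(self, mini):
        model, base = mini
        data = _cohort_data()
        # case5 needs mutation AND rna; P3 has no rna column
        out = personalize_cohort(model, base, data, "case5",
                                 mini_model_mapping())
        assert sorted(out) == ["P1", "P2"]
        # case2 needs mutation AND cna measurement; all three declared
        out2 = personalize_cohort(model, base, data, "case2",
                                  mini_model_mapping())
        assert sorted(out2) == ["P1", "P2", "P3"]

    def test_model_rules_never_modified(self, mini):
        model, base = mini
        before = write_bnd(model)
        personalize_cohort(model, base, _cohort_data(), "case6",
                           mini_model_mapping())
        assert write_bnd(model) == before

    def test_cohort_subset_gives_identical_settings(self, mini):
        """Personalization of a patient is independent of which other
        patients are in the cohort."""
        model, base = mini
        data = _cohort_data()
        full = personalize_cohort(model, base, data, "case5",
                                  mini_model_mapping())
        data_p1 = _cohort_data()
        data_p1.rna = data_p1.rna[["P1"]]
        data_p1.mutation_samples = ["P1"]
        solo = personalize_cohort(model, base, data_p1, "case5",
                                  mini_model_mapping())
        assert solo["P1"].node_settings == full["P1"].node_settings

    def test_mapping_validated_against_model(self, mini):
        model, base = mini
        bad = GeneNodeMapping({"NOT_A_NODE": ["TP53"]})
        with pytest.raises(ValueError, match="absent"):
            personalize_cohort(model, base, _cohort_data(), "case1", bad)

    def test_strategy_without_data_types_rejected(self, mini):
        model, base = mini
        with pytest.raises(ValueError, match="no data types"):
            personalize_cohort(
                model, base, _cohort_data(),
                PersonalizationStrategy("empty", (), ()),
                mini_model_mapping(),
            )


class TestPersonalizedDynamics:
    def test_p53_loss_increases_proliferation(self, mini):
        """Forcing the tumor suppressor off must raise the proliferation
        read-out relative to the generic model (exact solutions)."""
        from logiprofile.simulate import exact_distribution, exact_node_probabilities

        model, base = mini
        lost = apply_strict_nv(base, "p53", 0)
        p_base = exact_node_probabilities(
            exact_distribution(model, base, 40.0), model.nodes
        )
        p_lost = exact_node_probabilities(
            exact_distribution(model, lost, 40.0), model.nodes
        )
        assert p_lost["Proliferation"] > p_base["Proliferation"] + 0.1
        assert p_lost["Apoptosis"] < p_base["Apoptosis"]
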