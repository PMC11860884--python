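"""Transaction coding, Apriori and rule metrics against counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import count_rule_metrics, powerset_itemsets, random_record_sets
from effimine.markers import MarkerSpec
from effimine.mining import (
    AssociationRuleMiner,
    PatientRecord,
    TransactionTable,
    classify_rule_strength,
    code_improvement,
    derive_rules,
    mine_frequent_itemsets,
)


def crp_spec():
    return MarkerSpec(
        name="Hs-CRP", normal_low=0, normal_high=1,
        pre_median=36, pre_q1=16, pre_q3=66,
    )


class TestCodeImprovement:
    def test_strict_decrease_emits_item(self, fbg_spec):
        rec = PatientRecord("p1", True, {"FBG": (5.0, 4.5)})
        items = code_improvement(rec, [fbg_spec])
        assert items == {"XFC", "FBG_improved"}

    def test_tie_is_not_improvement(self, fbg_spec):
        rec = PatientRecord("p1", False, {"FBG": (4.5, 4.5)})
        assert code_improvement(rec, [fbg_spec]) == set()

    def test_marked_improvement_matches_cohort_shift(self):
        # the typical inflammatory-marker trajectory: strongly elevated
        # before, near-normal after
        rec = PatientRecord("p1", True, {"Hs-CRP": (36.0, 4.0)})
        items = code_improvement(rec, [crp_spec()])
        assert "Hs-CRP_improved" in items

    def test_low_is_bad_direction_mirrored(self):
        spec = MarkerSpec(
            name="HGB", normal_low=115, normal_high=150,
            pre_median=100, pre_q1=90, pre_q3=110, direction="low-is-bad",
        )
        rec = PatientRecord("p1", False, {"HGB": (100.0, 120.0)})
        assert code_improvement(rec, [spec]) == {"HGB_improved"}

    def test_tolerance_band_suppresses_small_changes(self, fbg_spec):
        rec = PatientRecord("p1", False, {"FBG": (5.0, 4.9)})
        assert code_improvement(rec, [fbg_spec], tolerance=0.05) == set()

    def test_unknown_marker_and_bad_values_rejected(self, fbg_spec):
        with pytest.raises(KeyError, match="ESR"):
            code_improvement(
                PatientRecord("p", False, {"ESR": (10.0, 5.0)}), [fbg_spec]
            )
        with pytest.raises(ValueError):
            code_improvement(
                PatientRecord("p", False, {"FBG": (-1.0, 2.0)}), [fbg_spec]
            )


class TestApriori:
    def test_saturated_table(self):
        table = TransactionTable.from_record_sets(
            [{"A", "B"}] * 4, items=["A", "B"]
        )
        found = dict(mine_frequent_itemsets(table, 0.5))
        assert found == {
            frozenset({"A"}): 1.0,
            frozenset({"B"}): 1.0,
            frozenset({"A", "B"}): 1.0,
        }

    def test_min_support_one_keeps_only_universal_itemsets(self):
        table = TransactionTable.from_record_sets(
            [{"A", "B"}, {"A"}, {"A", "B", "C"}], items=["A", "B", "C"]
        )
        found = [set(s) for s, _ in mine_frequent_itemsets(table, 1.0)]
        assert found == [{"A"}]

    def test_empty_table_yields_nothing(self):
        table = TransactionTable.from_record_sets([], items=["A"])
        assert mine_frequent_itemsets(table, 0.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_power_set_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        record_sets, items = random_record_sets(rng, 10, 5)
        table = TransactionTable.from_record_sets(record_sets, items=items)
        mined = mine_frequent_itemsets(table, 0.3)
        oracle = powerset_itemsets(record_sets, items, 0.3)
        assert [s for s, _ in mined] == [s for s, _ in oracle]
        for (_, sa), (_, sb) in zip(mined, oracle):
            assert sa == pytest.approx(sb, abs=1e-12)

    def test_raising_min_support_never_adds_itemsets(self):
        rng = np.random.default_rng(99)
        record_sets, items = random_record_sets(rng, 12, 5)
        table = TransactionTable.from_record_sets(record_sets, items=items)
        low = {s for s, _ in mine_frequent_itemsets(table, 0.2)}
        high = {s for s, _ in mine_frequent_itemsets(table, 0.5)}
        assert high <= low


class TestRules:
    def counting_table(self):
        # N=10: sigma(X)=4, sigma(X∪Y)=3, sigma(Y)=5
        records = (
            [{"X", "Y"}] * 3 + [{"X"}] + [{"Y"}] * 2 + [set()] * 4
        )
        return TransactionTable.from_record_sets(records, items=["X", "Y"])

    def test_metrics_match_direct_counts(self):
        rules = derive_rules(
            self.counting_table(), ["X"], ["Y"], min_support=0.0
        )
        (rule,) = rules
        assert rule.support == pytest.approx(0.30, abs=1e-12)
        assert rule.confidence == pytest.approx(0.75, abs=1e-12)
        assert rule.lift == pytest.approx(1.50, abs=1e-12)

    def test_universal_consequent_pins_confidence_and_lift(self):
        records = [{"X", "Y"}] * 2 + [{"Y"}] * 5
        table = TransactionTable.from_record_sets(records, items=["X", "Y"])
        (rule,) = derive_rules(table, ["X"], ["Y"], min_support=0.0)
        assert rule.confidence == 1.0
        assert rule.lift == 1.0

    def test_percent_rendering_layout(self, specs):
        frame = AssociationRuleMiner(self.counting_table(), ["X"], ["Y"]).fit(
            min_support=0.0
        ).frame()
        assert list(frame.columns) == [
            "LHS", "RHS", "support_pct", "confidence_pct", "lift", "strength"
        ]
        assert frame.loc[0, "support_pct"] == pytest.approx(30.0)

    def test_forced_overlap_rejected(self):
        table = TransactionTable.from_record_sets([{"X"}], items=["X"])
        with pytest.raises(ValueError, match="overlap"):
            derive_rules(table, ["X"], ["X"], min_support=0.0)

    def test_zero_antecedent_support_emits_no_rule(self):
        records = [{"Y"}] * 3
        table = TransactionTable.from_record_sets(records, items=["X", "Y"])
        assert derive_rules(table, ["X"], ["Y"], min_support=0.0) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_metric_identities_on_random_tables(self, seed):
        rng = np.random.default_rng(1000 + seed)
        record_sets, items = random_record_sets(rng, 12, 5)
        table = TransactionTable.from_record_sets(record_sets, items=items)
        rules = derive_rules(
            table, items[:2], items[2:], min_support=0.0, full_search=True
        )
        for rule in rules:
            assert rule.support <= rule.confidence <= 1.0
            sup_y = table.support(rule.consequent)
            assert rule.lift * sup_y == pytest.approx(rule.confidence, abs=1e-12)
            # confidence is invariant to records not containing X
            keep = [rs for rs in record_sets if set(rule.antecedent) <= rs]
            sub = TransactionTable.from_record_sets(keep, items=items)
            assert sub.support(rule.antecedent | rule.consequent) * sub.n / max(
                sub.sigma(rule.antecedent), 1
            ) == pytest.approx(rule.confidence, abs=1e-12)
            o_sup, o_conf, o_lift = count_rule_metrics(
                record_sets, rule.antecedent, rule.consequent
            )
            assert rule.support == pytest.approx(o_sup, abs=1e-12)
            assert rule.confidence == pytest.approx(o_conf, abs=1e-12)
            assert rule.lift == pytest.approx(o_lift, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.sets(st.sampled_from("ABCD")),
        min_size=1, max_size=10,
    )
)
def test_supports_match_enumeration_on_arbitrary_tables(record_sets):
    """Apriori finds exactly the brute-force frequent itemsets on any
    small transaction table."""
    items = ["A", "B", "C", "D"]
    table = TransactionTable.from_record_sets(record_sets, items=items)
    mined = mine_frequent_itemsets(table, 0.25)
    oracle = powerset_itemsets(
        [set(r) for r in record_sets], items, 0.25
    )
    assert [(s, pytest.approx(v, abs=1e-12)) for s, v in oracle] == mined


class TestStrength:
    @pytest.mark.parametrize(
        "confidence,lift,expected",
        [
            (0.65, 1.27, "strong"),
            (0.65, 1.00, "weak"),  # lift exactly 1 is not > 1
            (0.39, 1.123, "moderate"),
            (0.39, 0.901, "weak"),
            (0.61, 1.001, "strong"),
        ],
    )
    def test_classification_boundaries(self, confidence, lift, expected):
        assert classify_rule_strength(confidence, lift) == expected
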