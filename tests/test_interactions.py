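import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facstress.interactions import (
    COMBINATIONS,
    classify_interaction,
    exclusive_intersections,
    expected_combined_lfc,
    lfc_treatment_tree,
    tabulate_interactions,
)

COEFS = {
    "Salinity": 2.0, "Sediment": 0.0, "Flow": 1.0,
    "Salinity:Sediment": -0.5, "Salinity:Flow": -0.5, "Sediment:Flow": -0.5,
    "Salinity:Sediment:Flow": 0.3,
}


class TestExpectedCombined:
    def test_pairwise_sum_rule(self):
        assert expected_combined_lfc(COEFS, "Salinity:Flow") == 3.0

    def test_all_zero(self):
        zeros = dict.fromkeys(COEFS, 0.0)
        for combo in COMBINATIONS:
            assert expected_combined_lfc(zeros, combo) == 0.0

    def test_three_way_includes_all_lower_orders(self):
        c = dict.fromkeys(COEFS, 0.0)
        for f in ("Salinity", "Sediment", "Flow"):
            c[f] = 1.0
        for pair in ("Salinity:Sediment", "Salinity:Flow", "Sediment:Flow"):
            c[pair] = -0.5
        assert expected_combined_lfc(c, "Salinity:Sediment:Flow") == 1.5

    def test_unknown_combo_rejected(self):
        with pytest.raises(ValueError):
            expected_combined_lfc(COEFS, "Salinity:Temperature")


class TestClassify:
    @pytest.mark.parametrize(
        "expected,interaction,label",
        [(2.0, 1.0, "S+"), (2.0, -1.0, "A+"), (-2.0, 1.0, "A-"), (-2.0, -1.0, "S-")],
    )
    def test_four_quadrants(self, expected, interaction, label):
        assert classify_interaction(expected, interaction) == label

    def test_exhaustive_sign_grid(self):
        # every (sign(expected), sign(interaction)) cell maps per the rule
        grid = {
            (1, 1): "S+", (1, -1): "A+", (-1, 1): "A-", (-1, -1): "S-",
            (0, 1): "S+", (0, -1): "S-",
        }
        for (es, isn), label in grid.items():
            assert classify_interaction(es * 2.0, isn * 1.0) == label

    def test_sign_flip_symmetry(self):
        swap = {"S+": "S-", "S-": "S+", "A+": "A-", "A-": "A+"}
        for e, i in [(2.0, 1.0), (2.0, -1.0), (-2.0, 1.0), (0.0, 0.5)]:
            assert classify_interaction(-e, -i) == swap[classify_interaction(e, i)]

    def test_near_zero_interaction_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(1.0, 1e-9)


class TestTabulate:
    def test_empty_input_zero_table(self):
        empty = pd.DataFrame(columns=["gene", "combination", "expected_lfc",
                                      "interaction_lfc", "class", "padj"])
        tab = tabulate_interactions(empty)
        assert (tab.to_numpy() == 0).all()
        assert list(tab.columns) == list(COMBINATIONS)

    def test_totals_conserved(self):
        calls = pd.DataFrame({
            "gene": ["g1", "g2", "g3"],
            "combination": ["Salinity:Flow", "Salinity:Flow", "Sediment:Flow"],
            "expected_lfc": [1, 1, -1], "interaction_lfc": [1, -1, -1],
            "class": ["S+", "A+", "S-"], "padj": [0.01] * 3,
        })
        tab = tabulate_interactions(calls)
        assert tab.at["total", "Salinity:Flow"] == 2
        assert tab.at["total", "Sediment:Flow"] == 1
        assert tab.loc["total"].sum() == len(calls)


def brute_force_partition(sets):
    names = list(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for sig in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in sig)) if sig else set()
            outside = set().union(*(sets[n] for n in names if n not in sig), set())
            members = inside - outside
            if members:
                regions[sig] = members
    return regions


class TestExclusiveIntersections:
    def test_definition_example(self):
        part = exclusive_intersections({"A": {"g1", "g2"}, "B": {"g2"}})
        got = dict(zip(part["signature"], part["genes"]))
        assert got == {"A": ["g1"], "A&B": ["g2"]}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_partition_matches_bruteforce(self, seed, n_sets):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(25)]
        sets = {
            f"S{i}": {g for g in universe if rng.random() < 0.3}
            for i in range(n_sets)
        }
        part = exclusive_intersections(sets)
        # partition: disjoint and covering
        all_genes = [g for genes in part["genes"] for g in genes]
        assert len(all_genes) == len(set(all_genes))
        assert set(all_genes) == set().union(*sets.values())
        assert part["count"].sum() == len(set(all_genes))
        ref = brute_force_partition(sets)
        got = {tuple(sig.split("&")): set(g) for sig, g in
               zip(part["signature"], part["genes"])}
        assert got == ref

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError):
            exclusive_intersections({f"S{i}": {"g"} for i in range(17)})


class TestTreatmentTree:
    def test_identical_columns_merge_first(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [5.0, 9.0]})
        Z = lfc_treatment_tree(m)
        assert sorted(Z[0, :2]) == [0, 1]  # a and b merge at height 0
        assert Z[0, 2] == 0.0

    def test_hand_euclidean(self):
        m = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        Z = lfc_treatment_tree(m)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_row_permutation_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 5)))
        Z1 = lfc_treatment_tree(m)
        Z2 = lfc_treatment_tree(m.sample(frac=1, random_state=0))
        np.testing.assert_allclose(Z1, Z2)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            lfc_treatment_tree(pd.DataFrame({"a": [1.0]}))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            lfc_treatment_tree(pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]}))
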