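"""Node ages, PAS classification, RED, and stratified subsampling."""

import numpy as np
import pandas as pd
import pytest

from sedarch import chronology as ch
from sedarch import synthetic_data as sd
from sedarch.exceptions import MissingDataError, UltrametricityError

from conftest import make_tree, random_binary_tree, red_oracle


class TestNodeAges:
    def test_path_sums(self):
        tree = make_tree("((A:10,B:10):5,C:15);")
        ages = ch.node_ages(tree)
        by_age = sorted(a for n, a in ages.items() if not n.is_leaf())
        assert by_age == pytest.approx([10.0, 15.0])

    def test_cherry_root_age(self):
        tree = make_tree("(A:7,B:7);")
        ages = ch.node_ages(tree)
        assert ages[tree.seed_node] == pytest.approx(7.0)

    def test_non_ultrametric_raises_with_offenders(self):
        tree = make_tree("(A:10,B:9);")
        with pytest.raises(UltrametricityError) as err:
            ch.node_ages(tree)
        assert "B" in err.value.offenders or "A" in err.value.offenders


class TestLatestDivergence:
    def test_parent_ages(self):
        tree = make_tree("((A:10,B:10):5,C:15);")
        ages = ch.latest_divergence(tree)
        assert ages == pytest.approx({"A": 10.0, "B": 10.0, "C": 15.0})

    def test_cherry_tips_share_value(self):
        tree = make_tree("((A:3,B:3):4,(C:2,D:2):5);")
        ages = ch.latest_divergence(tree)
        assert ages["A"] == ages["B"]
        assert ages["C"] == ages["D"]

    def test_extremes_reported_from_parent_ages(self):
        # a tree whose tip parent ages span the catalog's printed extremes
        tree = make_tree(
            "((UBA5614:3195.8,(X:100,Y:100):3095.8):804.2,"
            "((Fen-1088:8.9,Z:8.9):1991.1,W:2000):2000);"
        )
        ages = ch.latest_divergence(tree)
        assert max(ages.values()) == pytest.approx(3195.8)
        assert min(ages.values()) == pytest.approx(8.9)
        assert ages["UBA5614"] == pytest.approx(3195.8)
        assert ages["Fen-1088"] == pytest.approx(8.9)


class TestClassifyPAS:
    @pytest.mark.parametrize("age, expected", [
        (600.0, "PAS"),
        (8.9, "extant"),
        (541.0, "extant"),     # boundary tie goes to extant
        (541.0001, "PAS"),
    ])
    def test_boundary_rule(self, age, expected):
        assert ch.classify_pas({"sp": age})["sp"] == expected

    def test_partition(self):
        rng = np.random.default_rng(0)
        ages = {f"s{i}": float(a) for i, a in
                enumerate(rng.uniform(0, 3000, 200))}
        classes = ch.classify_pas(ages)
        n_pas = sum(1 for c in classes.values() if c == "PAS")
        n_ext = sum(1 for c in classes.values() if c == "extant")
        assert n_pas + n_ext == len(ages)

    def test_recovers_planted_ancient_fraction(self):
        cfg = sd.SimulationConfig(seed=21, n_tips=200, ancient_fraction=0.4)
        tree, _, truth = sd.gen_time_tree(cfg)
        classes = ch.classify_pas(ch.latest_divergence(tree))
        frac = sum(1 for c in classes.values() if c == "PAS") / len(classes)
        assert frac == pytest.approx(0.4, abs=0.05)
        assert {s for s, c in classes.items() if c == "PAS"} \
            == set(truth["planted_ancient"])


class TestGroupSummary:
    def test_archaeal_style_contingency(self):
        # 55 Cryptozoic (46 sediment-only), 140 Phanerozoic (125 sediment-only)
        classification, groups = {}, {}
        i = 0
        for n, grp in ((46, "Sediment only"), (9, "Water only")):
            for _ in range(n):
                classification[f"s{i}"] = "PAS"; groups[f"s{i}"] = grp; i += 1
        for n, grp in ((125, "Sediment only"), (11, "Water only"), (4, "Shared")):
            for _ in range(n):
                classification[f"s{i}"] = "extant"; groups[f"s{i}"] = grp; i += 1
        out = ch.pas_group_summary(classification, groups)
        assert out["counts"].loc["PAS", "Sediment only"] == 46
        assert out["percentages"].loc["PAS", "Sediment only"] == 83.6
        assert out["percentages"].loc["PAS", "Sediment only"] > 80
        assert out["percentages"].loc["extant", "Sediment only"] == 89.3

    def test_empty_eon_no_division_error(self):
        out = ch.pas_group_summary({"a": "extant"}, {"a": "Shared"})
        assert out["counts"].loc["PAS"].sum() == 0
        assert (out["percentages"].loc["PAS"] == 0).all()

    def test_missing_group_raises(self):
        with pytest.raises(MissingDataError):
            ch.pas_group_summary({"a": "PAS"}, {})


class TestProportionCurves:
    def test_all_equal_ages_step_function(self):
        ages = {f"s{i}": 100.0 for i in range(10)}
        groups = {f"s{i}": "Sediment only" for i in range(10)}
        curves = ch.proportion_curves(ages, groups, [200.0, 100.0, 50.0, 0.0])
        assert curves["Sediment only"].tolist() == [0.0, 1.0, 1.0, 1.0]

    def test_single_point_grid_all_one(self):
        ages = {"a": 5.0, "b": 700.0}
        groups = {"a": "Water only", "b": "Water only"}
        curves = ch.proportion_curves(ages, groups, [0.0])
        assert (curves.loc[0.0] == 1.0).all()

    def test_boundary_value_matches_planted_fraction(self):
        cfg = sd.SimulationConfig(seed=7, n_tips=200, ancient_fraction=0.3)
        tree, group_df, truth = sd.gen_time_tree(cfg)
        ages = ch.latest_divergence(tree)
        groups = dict(zip(group_df["species_id"], group_df["group"]))
        grid = [3000.0, 541.0001, 0.0]
        curves = ch.proportion_curves(ages, groups, grid)
        pooled = sum(
            curves.loc[541.0001, g] * sum(1 for v in groups.values() if v == g)
            for g in curves.columns
        ) / len(ages)
        assert pooled == pytest.approx(truth["realized_ancient_fraction"], abs=1e-9)

    def test_nonincreasing_in_age(self):
        rng = np.random.default_rng(3)
        ages = {f"s{i}": float(a) for i, a in enumerate(rng.uniform(0, 2000, 50))}
        groups = {s: "Shared" for s in ages}
        grid = [2000.0, 1000.0, 500.0, 100.0, 0.0]
        curves = ch.proportion_curves(ages, groups, grid)
        assert (np.diff(curves["Shared"].to_numpy()) >= 0).all()


class TestRED:
    def test_two_leaf_tree(self):
        tree = make_tree("(A:1,B:1);")
        values = ch.red(tree)
        assert values[tree.seed_node] == 0.0
        for leaf in tree.leaf_node_iter():
            assert values[leaf] == 1.0

    def test_hand_evaluated_internal_node(self):
        tree = make_tree("((A:1,B:1):1,C:2);")
        values = ch.red(tree)
        internal = next(
            n for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        )
        assert values[internal] == pytest.approx(0.5)

    def test_matches_bruteforce_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            tree = random_binary_tree(rng, int(rng.integers(4, 51)))
            ours = ch.red(tree)
            oracle = red_oracle(tree)
            for node, expected in oracle.items():
                assert ours[node] == pytest.approx(expected, abs=1e-12)

    def test_invariants_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tree = random_binary_tree(rng, 30)
            values = ch.red(tree)
            assert values[tree.seed_node] == 0.0
            for node in tree.preorder_node_iter():
                assert -1e-12 <= values[node] <= 1.0 + 1e-12
                if node.parent_node is not None:
                    assert values[node] >= values[node.parent_node] - 1e-12

    def test_zero_length_path_raises(self):
        tree = make_tree("((A:0,B:0):0,C:0);")
        with pytest.raises(ValueError):
            ch.red(tree)


class TestStratifiedSubsample:
    def mag_table(self, sizes: dict) -> pd.DataFrame:
        rows = []
        for phylum, n in sizes.items():
            for i in range(n):
                rows.append({"mag_id": f"{phylum}_{i}", "phylum": phylum})
        return pd.DataFrame(rows)

    def test_exact_size_and_reps(self):
        mags = self.mag_table({"A": 300, "B": 120, "C": 80, "tiny": 10})
        draws = ch.stratified_subsample(mags, n_target=200, reps=15, seed=0)
        assert len(draws) == 15
        assert all(len(d) == 200 for d in draws)
        assert len(set(map(tuple, draws))) > 1  # independent draws differ

    def test_small_phyla_merged(self):
        mags = self.mag_table({"A": 200, "t1": 5, "t2": 5, "t3": 5})
        draws = ch.stratified_subsample(mags, n_target=100, min_phylum=30,
                                        reps=2, seed=1)
        merged_drawn = [m for m in draws[0] if not m.startswith("A")]
        # merged stratum (15 of 215) gets round(100·15/215) = 7 slots
        assert len(merged_drawn) == 7

    def test_largest_remainder_within_one_of_proportions(self):
        sizes = {"A": 511, "B": 263, "C": 91, "D": 135}
        alloc = ch.largest_remainder_allocation(sizes, 200)
        assert sum(alloc.values()) == 200
        total = sum(sizes.values())
        for s, n in sizes.items():
            assert abs(alloc[s] - 200 * n / total) < 1.0

    def test_single_stratum_simple_random_sample(self):
        mags = self.mag_table({"A": 50})
        draws = ch.stratified_subsample(mags, n_target=20, reps=3, seed=2)
        assert all(len(set(d)) == 20 for d in draws)

    def test_target_exceeding_table_raises(self):
        with pytest.raises(ValueError):
            ch.stratified_subsample(self.mag_table({"A": 10}), n_target=20)
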