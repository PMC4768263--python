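"""Decision-tree growth, termination rules, and forest regeneration."""

import numpy as np
import pandas as pd
import pytest

import coopharm as cp
from conftest import make_dataset, noise_dataset


class TestBestSplit:
    def test_planted_driver_selected_with_medians(
            self, planted_single_driver):
        ds = planted_single_driver
        hit = cp.best_split(ds.cells, ds.features, ds, "drugX")
        assert hit is not None
        feature, res = hit
        assert feature == cp.AlterationFeature("G", "MUT")
        assert res.p_value < 1e-6
        tree = cp.grow_tree(ds, "drugX")
        assert tree.root.median_left == pytest.approx(10.095)
        assert tree.root.median_right == pytest.approx(0.095)

    def test_threshold_rule_returns_none(self):
        rng = np.random.default_rng(3)
        ds = make_dataset({"G:MUT": [1] * 10 + [0] * 10},
                          {"E": rng.normal(size=20).tolist()},
                          {"d": rng.normal(size=20).tolist()})
        assert cp.best_split(ds.cells, ds.features, ds, "d") is None

    def test_identical_membership_breaks_ties_lexicographically(self):
        col = [1] * 10 + [0] * 10
        y = list(range(10, 20)) + list(range(10))
        ds = make_dataset({"B:MUT": col, "A:MUT": col},
                          {"E": [0.0] * 20}, {"d": [float(v) for v in y]})
        feature, _ = cp.best_split(ds.cells, ds.features, ds, "d")
        assert feature == cp.AlterationFeature("A", "MUT")

    def test_tiny_child_groups_not_evaluated(self):
        # only one altered cell: a 1-vs-n split is never tested
        ds = make_dataset({"G:MUT": [1] + [0] * 11},
                          {"E": [0.0] * 12},
                          {"d": [100.0] + list(map(float, range(11)))})
        assert cp.best_split(ds.cells, ds.features, ds, "d") is None

    def test_unknown_drug_errors(self, planted_single_driver):
        with pytest.raises(KeyError):
            cp.best_split(planted_single_driver.cells,
                          planted_single_driver.features,
                          planted_single_driver, "nope")


class TestGrowTree:
    def test_planted_fixture_grows_exactly_three_nodes(
            self, planted_single_driver):
        tree = cp.grow_tree(planted_single_driver, "drugX")
        nodes = cp.enumerate_nodes(tree)
        assert len(nodes) == 3
        assert tree.root.feature == cp.AlterationFeature("G", "MUT")
        assert tree.root.left.is_leaf and tree.root.right.is_leaf

    def test_two_level_conditional_feature_only_on_altered_branch(
            self, two_level_dataset):
        tree = cp.grow_tree(two_level_dataset, "drugX")
        assert tree.root.feature == cp.AlterationFeature("G1", "MUT")
        left_feats = {n.feature for n in _subtree(tree.root.left)
                      if n.feature is not None}
        right_feats = {n.feature for n in _subtree(tree.root.right)
                       if n.feature is not None}
        g2 = cp.AlterationFeature("G2", "MUT")
        assert g2 in left_feats
        assert g2 not in right_feats

    @pytest.mark.parametrize("seed", range(10))
    def test_pure_noise_rarely_splits(self, seed):
        tree = cp.grow_tree(noise_dataset(seed), "drugX")
        # false split probability ~0.1 per tree at alpha=0.001 x 100 tests;
        # individual seeds may split, the acceptance suite checks the rate
        assert tree.n_nodes in (1, 3, 5, 7)

    def test_partition_and_threshold_invariants(self, two_level_dataset):
        tree = cp.grow_tree(two_level_dataset, "drugX")
        for node in cp.enumerate_nodes(tree):
            if node.is_leaf:
                continue
            assert node.split_p < tree.params.p_threshold
            assert node.n_cells >= tree.params.min_node_size
            assert set(node.left.cells) | set(node.right.cells) == \
                set(node.cells)
            assert not set(node.left.cells) & set(node.right.cells)
            alt = two_level_dataset.alterations.loc[node.feature.key]
            assert all(alt[c] == 1 for c in node.left.cells)
            assert all(alt[c] == 0 for c in node.right.cells)

    def test_construction_is_deterministic(self, two_level_dataset):
        t1 = cp.grow_tree(two_level_dataset, "drugX")
        t2 = cp.grow_tree(two_level_dataset, "drugX")
        for a, b in zip(cp.enumerate_nodes(t1), cp.enumerate_nodes(t2)):
            assert (a.node_id, a.cells, a.feature, a.split_p) == \
                (b.node_id, b.cells, b.feature, b.split_p)

    def test_missing_responses_dropped_before_growth(
            self, planted_single_driver):
        ds = planted_single_driver
        ds.responses.loc["drugX", "C0"] = np.nan
        tree = cp.grow_tree(ds, "drugX")
        all_leaf_cells = [c for n in cp.enumerate_nodes(tree) if n.is_leaf
                          for c in n.cells]
        assert "C0" not in all_leaf_cells
        assert sorted(all_leaf_cells) == sorted(set(ds.cells) - {"C0"})

    def test_sensitizing_driver_reads_out_left_above_right(
            self, planted_single_driver):
        tree = cp.grow_tree(planted_single_driver, "drugX")
        assert tree.root.median_left > tree.root.median_right


def _subtree(node):
    out = []

    def walk(n):
        if n is None:
            return
        out.append(n)
        walk(n.left)
        walk(n.right)

    walk(node)
    return out


def two_driver_dataset(seed=5, n=40):
    """Two strong drivers with mutually exclusive carrier sets (as BRAF and
    KRAS mutations are in practice); G1's effect is larger than G2's, so
    tree 1 roots at G1 and the regrown tree 2 surfaces G2."""
    rng = np.random.default_rng(seed)
    g1 = np.array([1] * 18 + [0] * 22)
    g2 = np.array([0] * 18 + [1] * 18 + [0] * 4)
    y = 1.0 + 8.0 * g1 + 4.0 * g2 + rng.normal(0, 0.25, n)
    cells = [f"C{i}" for i in range(n)]
    return cp.PharmacogenomicDataset(
        alterations=pd.DataFrame(np.vstack([g1, g2]),
                                 index=["G1:MUT", "G2:MUT"], columns=cells),
        expression=pd.DataFrame(rng.normal(0, 1, (2, n)),
                                index=["E1", "E2"], columns=cells),
        responses=pd.DataFrame([y], index=["drugX"], columns=cells),
        metric=cp.SensitivityMetric.activity_area(),
        name="two_driver",
    )


class TestForest:
    def test_two_driver_fixture_yields_two_trees_in_effect_order(self):
        forest = cp.grow_forest(two_driver_dataset(), "drugX")
        assert len(forest) == 2
        assert forest.trees[0].root.feature == \
            cp.AlterationFeature("G1", "MUT")
        assert forest.trees[1].root.feature == \
            cp.AlterationFeature("G2", "MUT")

    def test_pure_noise_gives_empty_forest(self):
        # seed chosen arbitrarily; a non-splitting noise draw ends round 1
        for seed in range(5):
            forest = cp.grow_forest(noise_dataset(seed, n_cells=20,
                                                  n_features=10), "drugX")
            for t1 in forest.trees:
                assert not t1.is_stump

    def test_feature_sets_pairwise_disjoint(self, two_level_dataset):
        forest = cp.grow_forest(two_level_dataset, "drugX")
        used = [t.features_used() for t in forest.trees]
        for i in range(len(used)):
            for j in range(i + 1, len(used)):
                assert not used[i] & used[j]


class TestEnumerateNodes:
    def test_preorder_and_genotype_paths(self, two_level_dataset):
        tree = cp.grow_tree(two_level_dataset, "drugX")
        nodes = cp.enumerate_nodes(tree)
        assert nodes[0] is tree.root
        assert nodes[1] is tree.root.left
        assert nodes[1].path == ((tree.root.feature, "altered"),)
        # parent cell sets are reconstituted by their children at each level
        for node in nodes:
            if not node.is_leaf:
                assert sorted(node.left.cells + node.right.cells) == \
                    sorted(node.cells)

    def test_single_leaf(self, planted_single_driver):
        tree = cp.grow_tree(planted_single_driver, "drugX", candidates=[])
        assert cp.enumerate_nodes(tree) == [tree.root]


class TestTreeParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cp.TreeParams(p_threshold=1.5)
        with pytest.raises(ValueError):
            cp.TreeParams(min_node_size=3, min_child_size=2)
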