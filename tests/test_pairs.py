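"""First/second-biomarker criteria, pair assembly, cross-screen concordance."""

import pytest

import coopharm as cp


def _discover(seed: int, which: str = "A"):
    scen_a, scen_b = cp.default_two_dataset_scenario(seed)
    scen = scen_a if which == "A" else scen_b
    ds, truth = cp.generate(scen)
    pathways, targets, common = cp.default_support()
    model = cp.CooperativeBiomarkerModel(ds, pathways, targets, common)
    return model.fit(ds.drugs[0]), truth


def _mk_record(drug="drugX", node="root.alt", gene="M", r=-0.7, q=0.01):
    return cp.NodeCorrelationRecord(drug, node, "G:MUT=alt", gene, r,
                                    q, q, 50, True)


class TestSelectFirstBiomarkers:
    def test_sensitizing_common_gene_root_selected(self):
        res, truth = _discover(seed=11)
        selected = cp.select_first_biomarkers(
            res.forest, frozenset({"GD1"}))
        assert [f.key for _, f in selected] == ["GD1:MUT"]

    def test_desensitizing_root_rejected(self):
        res, _ = _discover(seed=11)
        tree = res.forest.trees[0]
        flipped = cp.DecisionTree(
            drug=tree.drug, dataset_name=tree.dataset_name,
            root=cp.TreeNode(
                node_id="root", cells=tree.root.cells,
                feature=tree.root.feature, split_p=tree.root.split_p,
                median_left=0.1, median_right=10.0, depth=0,
                left=tree.root.left, right=tree.root.right),
            params=tree.params)
        forest = cp.BiomarkerForest(tree.drug, tree.dataset_name,
                                    [flipped], [frozenset()])
        assert cp.select_first_biomarkers(forest, frozenset({"GD1"})) == []

    def test_gene_absent_from_common_list_rejected(self):
        res, _ = _discover(seed=11)
        assert cp.select_first_biomarkers(
            res.forest, frozenset({"OTHERGENE"})) == []


class TestAssemblePairs:
    def test_planted_scenario_recovers_pair_with_partner_drug(self):
        res, truth = _discover(seed=11)
        (driver, modulator, drug) = truth.planted_pairs[0]
        assert any(
            p.first_feature == driver and p.second_gene == modulator
            and p.drug_x == drug and p.drugs_y == {"drugY"}
            for p in res.pairs)
        pair = res.pairs[0]
        assert pair.flags.in_common_cancer_genes
        assert pair.flags.second_in_core_pathway
        assert pair.flags.second_druggable
        assert not pair.flags.cross_dataset_confirmed

    def test_undruggable_second_gene_kept_out_of_two_drug_view(self):
        res, _ = _discover(seed=11)
        pathways, _, common = cp.default_support()
        no_targets = cp.DrugTargetTable(frozenset())
        firsts = cp.select_first_biomarkers(res.forest, common)
        pairs = cp.assemble_pairs(firsts, res.negative_correlations,
                                  pathways, no_targets)
        assert pairs and all(not p.flags.second_druggable for p in pairs)
        assert cp.two_drug_view(pairs) == []

    def test_wildtype_node_records_yield_no_pairs(self):
        res, _ = _discover(seed=11)
        pathways, targets, common = cp.default_support()
        firsts = cp.select_first_biomarkers(res.forest, common)
        wt_id = res.forest.trees[0].root.right.node_id
        fake = [_mk_record(drug=res.drug, node=wt_id, gene="MOD1")]
        assert cp.assemble_pairs(firsts, fake, pathways, targets) == []

    def test_second_gene_never_equals_first_gene(self):
        res, _ = _discover(seed=11)
        pathways, targets, common = cp.default_support()
        firsts = cp.select_first_biomarkers(res.forest, common)
        alt_id = res.forest.trees[0].root.left.node_id
        fake = [_mk_record(drug=res.drug, node=alt_id, gene="GD1")]
        assert cp.assemble_pairs(firsts, fake, pathways, targets) == []

    def test_emitted_pairs_satisfy_invariants(self):
        res, _ = _discover(seed=13)
        for p in res.pairs:
            assert p.median_left > p.median_right
            assert p.correlation.r < 0 and p.correlation.significant
            assert p.flags.second_in_core_pathway
            assert bool(p.drugs_y) == p.flags.second_druggable
            assert p.first_feature.gene != p.second_gene

    def test_tightening_fdr_never_adds_pairs(self):
        scen_a, _ = cp.default_two_dataset_scenario(17)
        ds, _ = cp.generate(scen_a)
        pathways, targets, common = cp.default_support()
        loose = cp.CooperativeBiomarkerModel(
            ds, pathways, targets, common, fdr=0.05).fit(ds.drugs[0])
        tight = cp.CooperativeBiomarkerModel(
            ds, pathways, targets, common, fdr=0.005).fit(ds.drugs[0])
        loose_ids = {(p.first_feature, p.second_gene) for p in loose.pairs}
        tight_ids = {(p.first_feature, p.second_gene) for p in tight.pairs}
        assert tight_ids <= loose_ids


def _pair(first="G", second="M", drug_x="x1", drugs_y=frozenset({"y"})):
    return cp.BiomarkerPair(
        first_feature=cp.AlterationFeature(first, "MUT"),
        second_gene=second, drug_x=drug_x, drugs_y=frozenset(drugs_y),
        source_node="root.alt", source_path=f"{first}:MUT=alt",
        correlation=_mk_record(drug=drug_x, gene=second),
        median_left=5.0, median_right=1.0,
        flags=cp.pairs.PairFlags(True, True, bool(drugs_y), False))


class TestCrossDatasetConfirm:
    def _targets(self, records):
        return cp.DrugTargetTable(frozenset(records))

    def test_same_target_class_confirms(self):
        targets = self._targets({("x1", "T"), ("x2", "T")})
        a = [_pair(drug_x="x1")]
        b = [_pair(drug_x="x2")]
        confirmed, rep = cp.cross_dataset_confirm(a, b, targets)
        assert confirmed[0].flags.cross_dataset_confirmed
        assert (rep.shared, rep.jaccard) == (1, 1.0)

    def test_partial_overlap_jaccard(self):
        targets = self._targets({("x1", "T"), ("x2", "T")})
        a = [_pair(drug_x="x1")]
        b = [_pair(drug_x="x2"), _pair(first="H", second="N", drug_x="x2")]
        _, rep = cp.cross_dataset_confirm(a, b, targets)
        assert (rep.pairs_a, rep.pairs_b, rep.shared) == (1, 2, 1)
        assert rep.jaccard == pytest.approx(0.5)

    def test_different_target_class_does_not_confirm(self):
        targets = self._targets({("x1", "T1"), ("x2", "T2")})
        confirmed, rep = cp.cross_dataset_confirm(
            [_pair(drug_x="x1")], [_pair(drug_x="x2")], targets)
        assert not confirmed[0].flags.cross_dataset_confirmed
        assert rep.shared == 0 and rep.jaccard == 0.0

    def test_end_to_end_two_screen_confirmation(self):
        res_a, truth = _discover(seed=21, which="A")
        res_b, _ = _discover(seed=21, which="B")
        confirmed, rep = res_a.confirm_with(res_b)
        driver, modulator, _ = truth.planted_pairs[0]
        hit = [p for p in confirmed
               if p.gene_pair == (driver.gene, modulator)]
        assert hit and hit[0].flags.cross_dataset_confirmed
        assert rep.shared >= 1
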