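"""Model/Results facade over the discovery pipeline.

`CooperativeBiomarkerModel` is built from a screen plus its annotation
resources; `fit(drug)` runs forest growth, node-conditional correlation and
pair selection for one drug and returns a `DiscoveryResults` carrying every
intermediate artifact, a tabular view and a text `summary()`.  Two results
objects from independent screens can be reconciled with `confirm_with`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .correlation import (NodeCorrelationRecord, correlate_nodes,
                          filter_negative, records_to_frame)
from .io import (DrugTargetTable, GeneSetCollection, PharmacogenomicDataset)
from .pairs import (BiomarkerPair, ConcordanceReport, assemble_pairs,
                    cross_dataset_confirm, pairs_to_frame,
                    select_first_biomarkers, two_drug_view)
from .tree import BiomarkerForest, TreeParams, grow_forest

__all__ = ["CooperativeBiomarkerModel", "DiscoveryResults"]


class CooperativeBiomarkerModel:
    """Cooperative-biomarker discovery model for one pharmacogenomic screen.

    Parameters
    ----------
    dataset
        Aligned alteration/expression/response matrices with a declared
        sensitivity orientation.
    pathways
        Cancer core-pathway gene sets; only genes in the universe are
        tested as second biomarkers.
    drug_targets
        Drug -> target-gene table used for druggability and for matching
        drug classes across screens.
    common_cancer_genes
        Genes accepted as first biomarkers (recurrently mutated in cancer).
    tree_params, fdr, min_cells, bh_scope, all_forest_roots
        Tuning knobs forwarded to the tree / correlation / pair stages.
    """

    def __init__(self,
                 dataset: PharmacogenomicDataset,
                 pathways: GeneSetCollection,
                 drug_targets: DrugTargetTable,
                 common_cancer_genes: frozenset[str] | set[str],
                 tree_params: TreeParams | None = None,
                 fdr: float = 0.05,
                 min_cells: int = 5,
                 bh_scope: str = "per_node",
                 all_forest_roots: bool = False):
        self.dataset = dataset
        self.pathways = pathways
        self.drug_targets = drug_targets
        self.common_cancer_genes = frozenset(common_cancer_genes)
        self.tree_params = tree_params or TreeParams()
        self.fdr = fdr
        self.min_cells = min_cells
        self.bh_scope = bh_scope
        self.all_forest_roots = all_forest_roots

    def fit(self, drug: str) -> "DiscoveryResults":
        """Run the full discovery chain for one drug."""
        forest = grow_forest(self.dataset, drug, self.tree_params)
        correlations: list[NodeCorrelationRecord] = []
        for tree in forest.trees:
            correlations.extend(correlate_nodes(
                tree, self.dataset, self.pathways,
                fdr=self.fdr, min_cells=self.min_cells,
                bh_scope=self.bh_scope,
            ))
        negative = filter_negative(correlations)
        firsts = select_first_biomarkers(forest, self.common_cancer_genes,
                                         all_roots=self.all_forest_roots)
        pairs = assemble_pairs(firsts, negative, self.pathways,
                               self.drug_targets)
        return DiscoveryResults(model=self, drug=drug, forest=forest,
                                correlations=correlations,
                                negative_correlations=negative, pairs=pairs)

    def fit_all(self) -> dict[str, "DiscoveryResults"]:
        """Fit every drug in the screen; returns drug -> results."""
        return {drug: self.fit(drug) for drug in self.dataset.drugs}


@dataclass
class DiscoveryResults:
    """Everything `CooperativeBiomarkerModel.fit` produced for one drug."""

    model: CooperativeBiomarkerModel
    drug: str
    forest: BiomarkerForest
    correlations: list[NodeCorrelationRecord]
    negative_correlations: list[NodeCorrelationRecord]
    pairs: list[BiomarkerPair]

    @property
    def two_drug_pairs(self) -> list[BiomarkerPair]:
        return two_drug_view(self.pairs)

    def pairs_frame(self) -> pd.DataFrame:
        return pairs_to_frame(self.pairs)

    def correlations_frame(self) -> pd.DataFrame:
        return records_to_frame(self.correlations,
                                self.model.dataset.name)

    def confirm_with(self, other: "DiscoveryResults"
                     ) -> tuple[list[BiomarkerPair], ConcordanceReport]:
        """Confirm this screen's pairs against an independent screen."""
        confirmed, report = cross_dataset_confirm(
            self.pairs, other.pairs, self.model.drug_targets)
        self.pairs = confirmed
        return confirmed, report

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Cooperative biomarker discovery results",
            "=" * 47,
            f"dataset:        {ds.name} ({len(ds.cells)} cells, "
            f"{len(ds.features)} alteration features)",
            f"drug:           {self.drug} "
            f"(metric: {ds.metric.name}, higher_is_sensitive="
            f"{ds.metric.higher_is_sensitive})",
            f"forest:         {len(self.forest)} tree(s)",
        ]
        for i, tree in enumerate(self.forest.trees, start=1):
            root = tree.root
            if root.is_leaf:
                lines.append(f"  tree {i}: (no split)")
            else:
                lines.append(
                    f"  tree {i}: root {root.feature.key} "
                    f"(p={root.split_p:.3g}, median alt/wt = "
                    f"{root.median_left:.3f}/{root.median_right:.3f}), "
                    f"{tree.n_nodes} nodes"
                )
        n_sig = sum(rec.significant for rec in self.correlations)
        lines += [
            f"correlations:   {len(self.correlations)} (node, gene) tests, "
            f"{n_sig} significant, "
            f"{len(self.negative_correlations)} significant negative",
            f"pairs:          {len(self.pairs)} candidate(s), "
            f"{len(self.two_drug_pairs)} with a partner drug",
        ]
        for p in self.pairs:
            drugs_y = ",".join(sorted(p.drugs_y)) or "-"
            lines.append(
                f"  {p.first_feature.key} + {p.second_gene} "
                f"(drug X: {p.drug_x}; drug Y: {drugs_y}; "
                f"r={p.correlation.r:.3f}, "
                f"q={p.correlation.p_adjusted:.2e}, "
                f"confirmed={p.flags.cross_dataset_confirmed})"
            )
        return "\n".join(lines)
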