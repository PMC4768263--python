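"""Selection of cooperative biomarker pairs and cross-dataset confirmation.

A *first biomarker* is a recurrent genomic alteration whose carriers are
more sensitive to drug X: the root of the decision tree, required to be a
commonly mutated cancer gene and to sensitize (altered-branch median above
wild-type median in canonical units).  A *second biomarker* is a
core-pathway transcript whose high expression within the altered branch is
significantly associated with reduced sensitivity; if a drug Y inhibits it,
(X, Y) is a candidate two-drug combination.  Candidates are confirmed when
an independent screen recovers the same gene pair under a drug of the same
target class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .correlation import NodeCorrelationRecord
from .io import AlterationFeature, DrugTargetTable, GeneSetCollection
from .tree import BiomarkerForest, DecisionTree

__all__ = ["PairFlags", "BiomarkerPair", "ConcordanceReport",
           "select_first_biomarkers", "assemble_pairs",
           "cross_dataset_confirm", "two_drug_view", "pairs_to_frame",
           "pairs_from_frame"]


@dataclass(frozen=True)
class PairFlags:
    in_common_cancer_genes: bool
    second_in_core_pathway: bool
    second_druggable: bool
    cross_dataset_confirmed: bool


@dataclass(frozen=True)
class BiomarkerPair:
    """(first alteration, second transcript, drug X, candidate drugs Y)."""

    first_feature: AlterationFeature
    second_gene: str
    drug_x: str
    drugs_y: frozenset[str]
    source_node: str          # node id of the root's altered child
    source_path: str
    correlation: NodeCorrelationRecord
    median_left: float        # canonical, altered branch
    median_right: float       # canonical, wild-type branch
    flags: PairFlags

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.first_feature.gene, self.second_gene)


@dataclass(frozen=True)
class ConcordanceReport:
    """Gene-pair overlap between two screens' candidate lists."""

    pairs_a: int
    pairs_b: int
    shared: int
    shared_pairs: tuple[tuple[str, str, str], ...]  # (first, second, target class)
    jaccard: float


def select_first_biomarkers(forest: BiomarkerForest,
                            common_cancer_genes: frozenset[str] | set[str],
                            all_roots: bool = False
                            ) -> list[tuple[DecisionTree, AlterationFeature]]:
    """Root features qualifying as first biomarkers.

    A root qualifies when it sensitizes (median_left > median_right,
    canonical units) and its gene is a commonly mutated cancer gene.  By
    default only the first tree's root is considered; ``all_roots=True``
    widens the search to every regrown tree's root.
    """
    trees = forest.trees if all_roots else forest.trees[:1]
    selected = []
    for tree in trees:
        root = tree.root
        if root.is_leaf:
            continue
        if root.median_left is None or root.median_left <= root.median_right:
            continue
        if root.feature.gene not in common_cancer_genes:
            continue
        selected.append((tree, root.feature))
    return selected


def assemble_pairs(selected_firsts: list[tuple[DecisionTree, AlterationFeature]],
                   correlation_records: list[NodeCorrelationRecord],
                   pathways: GeneSetCollection,
                   drug_targets: DrugTargetTable) -> list[BiomarkerPair]:
    """Build candidate pairs from significant negative correlations at the
    root's *altered* child node.

    ``correlation_records`` must already be pathway-filtered and restricted
    to significant negative correlations (see
    :func:`coopharm.correlation.filter_negative`).  Pairs whose second gene
    has no known inhibitor are retained (``second_druggable=False``) but
    excluded from the two-drug view; a second gene equal to the first gene
    is never paired with itself.
    """
    pairs: list[BiomarkerPair] = []
    for tree, feature in selected_firsts:
        left = tree.root.left
        if left is None:
            continue
        for rec in correlation_records:
            if rec.drug != tree.drug or rec.node_id != left.node_id:
                continue
            if rec.gene == feature.gene:
                continue
            drugs_y = drug_targets.drugs_for(rec.gene)
            pairs.append(BiomarkerPair(
                first_feature=feature,
                second_gene=rec.gene,
                drug_x=tree.drug,
                drugs_y=drugs_y,
                source_node=left.node_id,
                source_path=left.path_string(),
                correlation=rec,
                median_left=tree.root.median_left,
                median_right=tree.root.median_right,
                flags=PairFlags(
                    in_common_cancer_genes=True,
                    second_in_core_pathway=rec.gene in pathways.universe,
                    second_druggable=bool(drugs_y),
                    cross_dataset_confirmed=False,
                ),
            ))
    pairs.sort(key=lambda p: (p.drug_x, p.first_feature.key, p.second_gene))
    return pairs


def two_drug_view(pairs: list[BiomarkerPair]) -> list[BiomarkerPair]:
    """Pairs actionable as an (X, Y) two-drug combination."""
    return [p for p in pairs if p.flags.second_druggable]


def _target_class(pair_a: BiomarkerPair, pair_b: BiomarkerPair,
                  drug_targets: DrugTargetTable) -> frozenset[str]:
    return drug_targets.targets_of(pair_a.drug_x) & \
        drug_targets.targets_of(pair_b.drug_x)


def cross_dataset_confirm(pairs_a: list[BiomarkerPair],
                          pairs_b: list[BiomarkerPair],
                          drug_targets: DrugTargetTable
                          ) -> tuple[list[BiomarkerPair], ConcordanceReport]:
    """Annotate ``pairs_a`` with confirmation against an independent screen.

    A pair is confirmed when the other screen contains the same
    (first gene, second gene) pair discovered under a drug X sharing at
    least one target gene — drug names differ between screens, the target
    class is the invariant.  The report counts unique gene-pair identities.
    """
    confirmed: list[BiomarkerPair] = []
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for pa in pairs_a:
        hit: frozenset[str] = frozenset()
        for pb in pairs_b:
            if pa.gene_pair != pb.gene_pair:
                continue
            cls = _target_class(pa, pb, drug_targets)
            if cls:
                hit = hit | cls
        if hit:
            confirmed.append(replace(
                pa, flags=replace(pa.flags, cross_dataset_confirmed=True)))
            shared[pa.gene_pair] = shared.get(pa.gene_pair, frozenset()) | hit
        else:
            confirmed.append(pa)

    ids_a = {p.gene_pair for p in pairs_a}
    ids_b = {p.gene_pair for p in pairs_b}
    n_shared = len(shared)
    denom = len(ids_a) + len(ids_b) - n_shared
    report = ConcordanceReport(
        pairs_a=len(ids_a),
        pairs_b=len(ids_b),
        shared=n_shared,
        shared_pairs=tuple(sorted(
            (first, second, ",".join(sorted(targets)))
            for (first, second), targets in shared.items()
        )),
        jaccard=(n_shared / denom) if denom > 0 else 0.0,
    )
    return confirmed, report


def pairs_from_frame(df: pd.DataFrame) -> list[BiomarkerPair]:
    """Rebuild pairs from the TSV tabulation written by ``pairs_to_frame``."""
    out: list[BiomarkerPair] = []
    for row in df.itertuples(index=False):
        drugs_y = frozenset(
            d for d in str(row.drugs_y).split(",")
            if d and d != "nan"
        ) if not pd.isna(row.drugs_y) else frozenset()
        rec = NodeCorrelationRecord(
            drug=row.drug_x, node_id="", node_path="", gene=row.second_gene,
            r=float(row.r), p_raw=float("nan"),
            p_adjusted=float(row.p_adjusted), n_cells=int(row.n_cells),
            significant=True,
        )
        out.append(BiomarkerPair(
            first_feature=AlterationFeature(row.first_gene, row.first_type),
            second_gene=row.second_gene,
            drug_x=row.drug_x,
            drugs_y=drugs_y,
            source_node="",
            source_path="",
            correlation=rec,
            median_left=float(row.median_left),
            median_right=float(row.median_right),
            flags=PairFlags(
                in_common_cancer_genes=bool(row.in_common_cancer_genes),
                second_in_core_pathway=bool(row.second_in_core_pathway),
                second_druggable=bool(row.second_druggable),
                cross_dataset_confirmed=bool(row.cross_dataset_confirmed),
            ),
        ))
    return out


def pairs_to_frame(pairs: list[BiomarkerPair]) -> pd.DataFrame:
    """Tabulate pairs for TSV export."""
    return pd.DataFrame([
        {"first_gene": p.first_feature.gene,
         "first_type": p.first_feature.alteration_type,
         "second_gene": p.second_gene,
         "drug_x": p.drug_x,
         "drugs_y": ",".join(sorted(p.drugs_y)),
         "r": p.correlation.r,
         "p_adjusted": p.correlation.p_adjusted,
         "n_cells": p.correlation.n_cells,
         "median_left": p.median_left,
         "median_right": p.median_right,
         "in_common_cancer_genes": p.flags.in_common_cancer_genes,
         "second_in_core_pathway": p.flags.second_in_core_pathway,
         "second_druggable": p.flags.second_druggable,
         "cross_dataset_confirmed": p.flags.cross_dataset_confirmed}
        for p in pairs
    ])
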