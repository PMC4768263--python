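"""Drug-specific decision trees over genomic alterations.

Each tree is grown on one drug's canonical sensitivity profile.  At every
node the candidate alteration best separating sensitive from insensitive
cells is chosen by the smallest two-sided Mann-Whitney p-value; cells
carrying the alteration go to the *left* child, wild-type cells to the
right.  Growth stops when no candidate reaches ``p < p_threshold`` or a node
falls below ``min_node_size`` cells.

The *forest* extension removes every biomarker used by an existing tree and
regrows, repeating until a round yields no split at all — surfacing
secondary drivers that the first tree's greedy choices would otherwise mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import AlterationFeature, PharmacogenomicDataset, canonical_sensitivity
from .stats import RankTestResult, mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = ["TreeParams", "TreeNode", "DecisionTree", "BiomarkerForest",
           "best_split", "grow_tree", "grow_forest", "enumerate_nodes"]


@dataclass(frozen=True)
class TreeParams:
    """Growth-termination and test-method knobs.

    p_threshold      largest admissible split p-value (default 0.001)
    min_node_size    smallest cell count a node may have and still be split
    min_child_size   smallest admissible child group for an evaluated split;
                     a 1-vs-n rank test is meaningless, hence the floor of 2
    exact_test_max_n group-size ceiling for the exact U distribution
    """

    p_threshold: float = 0.001
    min_node_size: int = 5
    min_child_size: int = 2
    exact_test_max_n: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_node_size < 2 * self.min_child_size:
            raise ValueError("min_node_size must be >= 2 * min_child_size")


@dataclass
class TreeNode:
    """One node: a cell subset, its splitting feature (None for a leaf),
    the split p-value and the two child medians in canonical units."""

    node_id: str
    cells: tuple[str, ...]
    feature: Optional[AlterationFeature]
    split_p: Optional[float]
    median_left: Optional[float]
    median_right: Optional[float]
    depth: int
    left: Optional["TreeNode"]
    right: Optional["TreeNode"]
    #: (feature, branch) steps from the root; branch is "altered"|"wildtype"
    path: tuple[tuple[AlterationFeature, str], ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def path_string(self) -> str:
        return ";".join(
            f"{feat.key}={'alt' if branch == 'altered' else 'wt'}"
            for feat, branch in self.path
        ) or "(root)"


@dataclass
class DecisionTree:
    drug: str
    dataset_name: str
    root: TreeNode
    params: TreeParams

    def nodes(self) -> list[TreeNode]:
        return enumerate_nodes(self)

    def features_used(self) -> frozenset[AlterationFeature]:
        return frozenset(n.feature for n in self.nodes() if not n.is_leaf)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes())

    @property
    def is_stump(self) -> bool:
        """True when no split was found at all (single-leaf tree)."""
        return self.root.is_leaf


@dataclass
class BiomarkerForest:
    """Trees from successive regrow-after-removal rounds for one drug."""

    drug: str
    dataset_name: str
    trees: list[DecisionTree]
    excluded_per_round: list[frozenset[AlterationFeature]]

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _find_best_split(cells_idx: np.ndarray,
                     y: np.ndarray,
                     alt: np.ndarray,
                     features: Sequence[AlterationFeature],
                     candidate_rows: Sequence[int],
                     params: TreeParams):
    """Best (feature row, RankTestResult) among candidates, or None.

    Deterministic tie-break: smaller p, then larger |median difference|,
    then lexicographic (gene, type).
    """
    best = None  # (p, -abs_med_diff, gene, type, row, result)
    y_node = y[cells_idx]
    for row in candidate_rows:
        mask = alt[row, cells_idx] == 1
        n_alt = int(mask.sum())
        n_wt = mask.size - n_alt
        if n_alt < params.min_child_size or n_wt < params.min_child_size:
            continue
        res = mann_whitney_u(y_node[mask], y_node[~mask],
                             exact_max_n=params.exact_test_max_n)
        med_diff = abs(float(np.median(y_node[mask]))
                       - float(np.median(y_node[~mask])))
        feat = features[row]
        key = (res.p_value, -med_diff, feat.gene, feat.alteration_type)
        if best is None or key < best[0]:
            best = (key, row, res)
    if best is None or best[2].p_value >= params.p_threshold:
        return None
    return best[1], best[2]


def best_split(cells: Iterable[str],
               candidates: Iterable[AlterationFeature],
               dataset: PharmacogenomicDataset,
               drug: str,
               params: TreeParams = TreeParams()
               ) -> Optional[tuple[AlterationFeature, RankTestResult]]:
    """Evaluate every candidate feature on ``cells`` and return the one with
    the smallest two-sided U-test p-value, or None if nothing qualifies.

    Only splits whose altered and wild-type subgroups (over cells with a
    non-missing response for ``drug``) both reach ``min_child_size`` are
    evaluated.
    """
    y_full = canonical_sensitivity(dataset, drug)
    cell_pos = {c: i for i, c in enumerate(dataset.cells)}
    idx = np.array([cell_pos[c] for c in cells
                    if c in cell_pos and np.isfinite(y_full.iloc[cell_pos[c]])],
                   dtype=int)
    alt = dataset.alterations.to_numpy()
    feat_row = {f: i for i, f in enumerate(dataset.features)}
    rows = sorted(
        (feat_row[f] for f in candidates if f in feat_row),
        key=lambda r: (dataset.features[r].gene,
                       dataset.features[r].alteration_type),
    )
    hit = _find_best_split(idx, y_full.to_numpy(), alt, dataset.features,
                           rows, params)
    if hit is None:
        return None
    row, res = hit
    return dataset.features[row], res


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------

def grow_tree(dataset: PharmacogenomicDataset,
              drug: str,
              candidates: Optional[Iterable[AlterationFeature]] = None,
              params: TreeParams = TreeParams()) -> DecisionTree:
    """Grow one decision tree for ``drug`` by recursive rank-test splitting.

    Cells with a missing response for the drug are dropped before growth.
    A feature already used on the current root-to-node path is not offered
    again on that path (a binary feature cannot split twice), but remains
    available on other paths.  Construction is fully deterministic.
    """
    y_full = canonical_sensitivity(dataset, drug)
    y = y_full.to_numpy()
    alt = dataset.alterations.to_numpy()
    features = dataset.features
    cells = np.array(dataset.cells)
    root_idx = np.flatnonzero(np.isfinite(y))

    if candidates is None:
        cand_rows = list(range(len(features)))
    else:
        feat_row = {f: i for i, f in enumerate(features)}
        cand_rows = [feat_row[f] for f in candidates if f in feat_row]
    cand_rows = sorted(cand_rows, key=lambda r: (features[r].gene,
                                                 features[r].alteration_type))

    def build(idx: np.ndarray, node_id: str, depth: int,
              path: tuple, used_rows: frozenset[int]) -> TreeNode:
        cell_names = tuple(cells[idx])
        if idx.size < params.min_node_size:
            return TreeNode(node_id, cell_names, None, None, None, None,
                            depth, None, None, path)
        rows = [r for r in cand_rows if r not in used_rows]
        hit = _find_best_split(idx, y, alt, features, rows, params)
        if hit is None:
            return TreeNode(node_id, cell_names, None, None, None, None,
                            depth, None, None, path)
        row, res = hit
        feat = features[row]
        mask = alt[row, idx] == 1
        left_idx, right_idx = idx[mask], idx[~mask]
        med_l = float(np.median(y[left_idx]))
        med_r = float(np.median(y[right_idx]))
        child_used = used_rows | {row}
        left = build(left_idx, node_id + ".alt", depth + 1,
                     path + ((feat, "altered"),), child_used)
        right = build(right_idx, node_id + ".wt", depth + 1,
                      path + ((feat, "wildtype"),), child_used)
        return TreeNode(node_id, cell_names, feat, res.p_value,
                        med_l, med_r, depth, left, right, path)

    root = build(root_idx, "root", 0, (), frozenset())
    return DecisionTree(drug=drug, dataset_name=dataset.name,
                        root=root, params=params)


def grow_forest(dataset: PharmacogenomicDataset,
                drug: str,
                params: TreeParams = TreeParams(),
                candidates: Optional[Iterable[AlterationFeature]] = None
                ) -> BiomarkerForest:
    """Regrow trees, excluding every feature used by earlier trees, until a
    round finds no split; the empty round's stump is not kept."""
    all_candidates = frozenset(candidates) if candidates is not None \
        else frozenset(dataset.features)
    trees: list[DecisionTree] = []
    excluded_per_round: list[frozenset[AlterationFeature]] = []
    excluded: frozenset[AlterationFeature] = frozenset()
    while True:
        remaining = all_candidates - excluded
        if not remaining:
            break
        tree = grow_tree(dataset, drug, remaining, params)
        if tree.is_stump:
            break
        trees.append(tree)
        excluded_per_round.append(excluded)
        excluded = excluded | tree.features_used()
    logger.info("forest for drug %s on %s: %d tree(s)",
                drug, dataset.name, len(trees))
    return BiomarkerForest(drug=drug, dataset_name=dataset.name,
                           trees=trees, excluded_per_round=excluded_per_round)


def enumerate_nodes(tree: DecisionTree) -> list[TreeNode]:
    """All nodes in deterministic pre-order (node, left subtree, right)."""
    out: list[TreeNode] = []

    def walk(node: Optional[TreeNode]) -> None:
        if node is None:
            return
        out.append(node)
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    return out
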