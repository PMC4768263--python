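"""Node-conditional expression/sensitivity correlation with per-node FDR.

For every tree node large enough to support it, the expression of each
core-pathway gene is correlated (Pearson) with canonical drug sensitivity
across that node's cells, and Benjamini-Hochberg adjustment is applied to
the genes tested at that node.  The biologically interesting signal is a
gene that correlates *within* an altered subpopulation but not outside it —
a candidate modulator of the drug's effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection, PharmacogenomicDataset, canonical_sensitivity
from .stats import bh_adjust
from .tree import DecisionTree, enumerate_nodes

logger = logging.getLogger(__name__)

__all__ = ["NodeCorrelationRecord", "correlate_nodes", "filter_negative",
           "records_to_frame"]


@dataclass(frozen=True)
class NodeCorrelationRecord:
    """One (node, gene) Pearson result with raw and BH-adjusted p."""

    drug: str
    node_id: str
    node_path: str
    gene: str
    r: float
    p_raw: float
    p_adjusted: float
    n_cells: int
    significant: bool


def _pearson_vectorized(expr: np.ndarray, y: np.ndarray):
    """Row-wise Pearson of ``expr`` (genes x cells) against ``y``.

    Returns (r, p, tested_mask); rows with zero variance are masked out.
    p uses the same t transform as :func:`coopharm.stats.pearson`.
    """
    n = y.size
    yc = y - y.mean()
    y_ss = float(np.dot(yc, yc))
    xc = expr - expr.mean(axis=1, keepdims=True)
    x_ss = np.einsum("ij,ij->i", xc, xc)
    tested = (x_ss > 0) & (y_ss > 0)
    r = np.full(expr.shape[0], np.nan)
    denom = np.sqrt(x_ss[tested] * y_ss)
    r[tested] = xc[tested] @ yc / denom
    r = np.clip(r, -1.0, 1.0)

    tiny = np.nextafter(0.0, 1.0)
    p = np.ones_like(r)
    rt = r[tested]
    with np.errstate(divide="ignore"):
        t = rt * np.sqrt((n - 2) / np.maximum(1.0 - rt * rt, 0.0))
    pt = 2.0 * sps.t.sf(np.abs(t), n - 2)
    pt[np.abs(rt) >= 1.0] = tiny
    p[tested] = np.clip(pt, tiny, 1.0)
    return r, p, tested


def correlate_nodes(tree: DecisionTree,
                    dataset: PharmacogenomicDataset,
                    pathways: GeneSetCollection,
                    fdr: float = 0.05,
                    min_cells: int = 5,
                    bh_scope: str = "per_node") -> list[NodeCorrelationRecord]:
    """Correlate core-pathway gene expression with sensitivity at each node.

    Genes are restricted to the intersection of the expression matrix and
    the pathway universe *before* testing.  BH adjustment is applied within
    each node by default (``bh_scope="per_node"``); ``"per_tree"`` pools all
    (node, gene) tests of the tree into one adjustment.  Nodes smaller than
    ``min_cells`` are skipped, as are zero-variance genes (counted in a log
    line).
    """
    if bh_scope not in ("per_node", "per_tree"):
        raise ValueError("bh_scope must be 'per_node' or 'per_tree'")
    if tree.dataset_name != dataset.name:
        raise ValueError(
            f"tree was grown on dataset {tree.dataset_name!r}, "
            f"got {dataset.name!r}"
        )
    roster = set(dataset.cells)
    genes = sorted(set(dataset.expression.index) & set(pathways.universe))
    if not genes:
        logger.warning("no expression gene lies in the pathway universe")
        return []

    y_full = canonical_sensitivity(dataset, tree.drug)
    cell_pos = {c: i for i, c in enumerate(dataset.cells)}
    expr_all = dataset.expression.loc[genes].to_numpy()
    y_all = y_full.to_numpy()

    records: list[NodeCorrelationRecord] = []
    n_skipped = 0
    for node in enumerate_nodes(tree):
        if node.n_cells < min_cells:
            continue
        missing = [c for c in node.cells if c not in roster]
        if missing:
            raise ValueError(
                f"tree node {node.node_id} references cells absent from the "
                f"dataset: {missing[:3]}"
            )
        idx = np.array([cell_pos[c] for c in node.cells], dtype=int)
        y = y_all[idx]
        r, p, tested = _pearson_vectorized(expr_all[:, idx], y)
        n_skipped += int((~tested).sum())
        t_idx = np.flatnonzero(tested)
        if t_idx.size == 0:
            continue
        if bh_scope == "per_node":
            p_adj = bh_adjust(p[t_idx])
        else:
            p_adj = np.full(t_idx.size, np.nan)  # filled after the loop
        for k, gi in enumerate(t_idx):
            records.append(NodeCorrelationRecord(
                drug=tree.drug, node_id=node.node_id,
                node_path=node.path_string(), gene=genes[gi],
                r=float(r[gi]), p_raw=float(p[gi]),
                p_adjusted=float(p_adj[k]) if bh_scope == "per_node" else np.nan,
                n_cells=node.n_cells,
                significant=bool(p_adj[k] < fdr) if bh_scope == "per_node"
                else False,
            ))
    if bh_scope == "per_tree" and records:
        adj = bh_adjust([rec.p_raw for rec in records])
        records = [replace(rec, p_adjusted=float(a), significant=bool(a < fdr))
                   for rec, a in zip(records, adj)]
    if n_skipped:
        logger.info("skipped %d zero-variance (node, gene) tests", n_skipped)
    logger.info("correlated %d pathway genes over tree nodes for drug %s "
                "(BH scope: %s)", len(genes), tree.drug, bh_scope)
    return records


def filter_negative(records: list[NodeCorrelationRecord]
                    ) -> list[NodeCorrelationRecord]:
    """Keep significant records with r < 0: high expression associated with
    low canonical sensitivity — the resistance-modulator direction."""
    return [rec for rec in records if rec.significant and rec.r < 0]


def records_to_frame(records: list[NodeCorrelationRecord],
                     dataset_name: str = "") -> pd.DataFrame:
    """Tabulate records for TSV export."""
    return pd.DataFrame([
        {"drug": rec.drug, "dataset": dataset_name, "node_id": rec.node_id,
         "node_path": rec.node_path, "gene": rec.gene, "r": rec.r,
         "p_raw": rec.p_raw, "p_adjusted": rec.p_adjusted,
         "n_cells": rec.n_cells, "significant": rec.significant}
        for rec in records
    ])
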