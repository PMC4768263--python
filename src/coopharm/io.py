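"""Core data model and file I/O for pharmacogenomic screens.

The package works on three aligned matrices per screen — a binary genomic
alteration matrix (feature x cell), a continuous expression matrix
(gene x cell), and a drug-response table (drug x cell) — together with a
declared sensitivity orientation.  Screens report sensitivity on different
scales (activity area, where higher means more sensitive; log IC50, where
lower does), so every downstream computation consumes *canonical* sensitivity,
in which higher always means more sensitive.

File dialects are plain delimited text: TSV matrices with row/column headers,
standard GMT gene sets, and a two-column drug->target table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of alteration-type codes: point mutation, copy-number
#: amplification, copy-number deletion.  Amplification and deletion of the
#: same gene are biologically opposite events and are kept as separate
#: binary features; the same gene may therefore appear under several types.
ALTERATION_TYPES = ("MUT", "AMP", "DEL")

_TYPE_ALIASES = {
    "MUT": "MUT", "MUTATION": "MUT",
    "AMP": "AMP", "AMPLIFICATION": "AMP",
    "DEL": "DEL", "DELETION": "DEL",
}


@dataclass(frozen=True, order=True)
class AlterationFeature:
    """A binary genomic feature: (gene, alteration type).

    The pair is the feature identity — ``("EGFR", "MUT")`` and
    ``("EGFR", "AMP")`` are distinct features.
    """

    gene: str
    alteration_type: str

    def __post_init__(self) -> None:
        gene = self.gene.strip()
        if not gene:
            raise ValueError("AlterationFeature.gene must be non-empty")
        object.__setattr__(self, "gene", gene)
        code = _TYPE_ALIASES.get(self.alteration_type.strip().upper())
        if code is None:
            raise ValueError(
                f"unknown alteration type {self.alteration_type!r}; "
                f"expected one of {ALTERATION_TYPES}"
            )
        object.__setattr__(self, "alteration_type", code)

    @property
    def key(self) -> str:
        """Row-header encoding used in the alteration TSV, ``GENE:TYPE``."""
        return f"{self.gene}:{self.alteration_type}"

    @classmethod
    def from_key(cls, key: str) -> "AlterationFeature":
        gene, sep, typ = key.rpartition(":")
        if not sep or not gene:
            raise ValueError(
                f"alteration row header {key!r} is not of the form GENE:TYPE"
            )
        return cls(gene, typ)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


@dataclass(frozen=True)
class SensitivityMetric:
    """A named drug-sensitivity scale and its orientation.

    ``higher_is_sensitive=True`` suits activity-area-like metrics;
    ``False`` suits (log) IC50-like metrics.
    """

    name: str
    higher_is_sensitive: bool

    #: Convenience constructors for the two common screen conventions.
    @classmethod
    def activity_area(cls) -> "SensitivityMetric":
        return cls("activity_area", True)

    @classmethod
    def ln_ic50(cls) -> "SensitivityMetric":
        return cls("ln_IC50", False)


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class PharmacogenomicDataset:
    """Aligned alteration / expression / response matrices over one roster.

    All three matrices share the identical, ordered cell-line roster.
    Alteration entries are 0/1; expression is real; responses are real with
    NaN marking missing measurements (a cell missing drug X's response is
    excluded from that drug's analyses only).
    """

    alterations: pd.DataFrame  # index: "GENE:TYPE" keys, columns: cells
    expression: pd.DataFrame   # index: gene symbols, columns: cells
    responses: pd.DataFrame    # index: drug names, columns: cells
    metric: SensitivityMetric
    name: str = "dataset"

    def __post_init__(self) -> None:
        cells = list(self.alterations.columns)
        for label, df in (("expression", self.expression),
                          ("responses", self.responses)):
            if list(df.columns) != cells:
                raise ValueError(
                    f"{label} matrix cell roster differs from the alteration "
                    f"matrix roster (alignment is required)"
                )
        _check_unique(cells, "cell")
        _check_unique(self.alterations.index, "alteration feature")
        _check_unique(self.expression.index, "expression gene")
        _check_unique(self.responses.index, "drug")
        vals = self.alterations.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary alteration value {vals[i, j]!r} at "
                f"feature {self.alterations.index[i]!r}, "
                f"cell {self.alterations.columns[j]!r}"
            )
        if not np.isfinite(self.expression.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        resp = self.responses.to_numpy()
        if np.isinf(resp).any():
            raise ValueError("response matrix contains infinite values")
        # parse/validate feature keys once
        self.features: list[AlterationFeature] = [
            AlterationFeature.from_key(k) for k in self.alterations.index
        ]

    @property
    def cells(self) -> list[str]:
        return list(self.alterations.columns)

    @property
    def drugs(self) -> list[str]:
        return list(self.responses.index)

    def alteration_vector(self, feature: AlterationFeature) -> pd.Series:
        return self.alterations.loc[feature.key]


def canonical_sensitivity(dataset: PharmacogenomicDataset,
                          drug: str) -> pd.Series:
    """Per-cell sensitivity with *higher = more sensitive*, NaN preserved.

    Lower-is-sensitive metrics (e.g. ln IC50) are negated; this is the only
    place orientation is consulted, making downstream code metric-agnostic.
    """
    if drug not in dataset.responses.index:
        raise KeyError(
            f"unknown drug {drug!r}; available: {sorted(dataset.drugs)}"
        )
    row = dataset.responses.loc[drug].astype(float)
    return row if dataset.metric.higher_is_sensitive else -row


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. cancer core pathways) with a membership universe."""

    sets: dict[str, frozenset[str]]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __contains__(self, gene: str) -> bool:
        return any(gene in members for members in self.sets.values())


@dataclass
class DrugTargetTable:
    """Deduplicated (drug, target gene) records with lookup in both directions."""

    records: frozenset[tuple[str, str]]

    def targets_of(self, drug: str) -> frozenset[str]:
        return frozenset(t for d, t in self.records if d == drug)

    def drugs_for(self, target: str) -> frozenset[str]:
        return frozenset(d for d, t in self.records if t == target)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, value_name: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], f"column header in {path.name}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str).str.strip()
    df.columns = [c.strip() for c in header[1:]]
    _check_unique(df.index, f"row header in {path.name}")
    return df


def read_dataset(alteration_path: str | Path,
                 expression_path: str | Path,
                 response_path: str | Path,
                 metric: SensitivityMetric,
                 name: str = "dataset") -> PharmacogenomicDataset:
    """Read the three TSV matrices and align them on their shared cells.

    The roster is the intersection of the three files' cell columns, in the
    alteration file's order; cells absent from any file are dropped with a
    warning.  An empty intersection is a fatal error.
    """
    alt = _read_matrix(alteration_path, "alteration")
    expr = _read_matrix(expression_path, "expression")
    resp = _read_matrix(response_path, "response")

    common = [c for c in alt.columns if c in set(expr.columns) & set(resp.columns)]
    if not common:
        raise ValueError(
            "no cell lines shared by the alteration, expression and "
            "response files"
        )
    dropped = (set(alt.columns) | set(expr.columns) | set(resp.columns)) - set(common)
    if dropped:
        logger.warning(
            "dropping %d cell(s) absent from at least one matrix: %s",
            len(dropped), ", ".join(sorted(dropped)),
        )
    return PharmacogenomicDataset(
        alterations=alt[common],
        expression=expr[common].astype(float),
        responses=resp[common].astype(float),
        metric=metric,
        name=name,
    )


def write_dataset(dataset: PharmacogenomicDataset, directory: str | Path,
                  prefix: str | None = None) -> dict[str, Path]:
    """Write the three matrices as TSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or dataset.name
    paths = {
        "alterations": directory / f"{prefix}.alterations.tsv",
        "expression": directory / f"{prefix}.expression.tsv",
        "responses": directory / f"{prefix}.responses.tsv",
    }
    dataset.alterations.to_csv(paths["alterations"], sep="\t",
                               index_label="feature")
    dataset.expression.to_csv(paths["expression"], sep="\t",
                              index_label="gene")
    dataset.responses.to_csv(paths["responses"], sep="\t", index_label="drug")
    return paths


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs at least "
                    f"name, description and one member gene"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets[name] = members
    return GeneSetCollection(sets)


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a two-column TSV (header ``drug<TAB>target``) of drug-target pairs."""
    records: set[tuple[str, str]] = set()
    with open(path) as fh:
        next(fh)  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected non-empty "
                    f"'drug<TAB>target' fields"
                )
            records.add((fields[0].strip(), fields[1].strip()))
    return DrugTargetTable(frozenset(records))


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\ttarget\n")
        for drug, target in sorted(table.records):
            fh.write(f"{drug}\t{target}\n")


def read_common_cancer_genes(path: str | Path) -> frozenset[str]:
    """Read a one-symbol-per-line gene list (commonly mutated cancer genes)."""
    with open(path) as fh:
        return frozenset(g.strip() for g in fh if g.strip())


# ---------------------------------------------------------------------------
# tree (de)serialization — schema shared with the tree module
# ---------------------------------------------------------------------------

def _node_to_dict(node) -> dict:
    return {
        "node_id": node.node_id,
        "feature": (
            None if node.feature is None
            else {"gene": node.feature.gene, "type": node.feature.alteration_type}
        ),
        "p_value": node.split_p,
        "cells": list(node.cells),
        "median_canonical_left": node.median_left,
        "median_canonical_right": node.median_right,
        "left": _node_to_dict(node.left) if node.left is not None else None,
        "right": _node_to_dict(node.right) if node.right is not None else None,
    }


def _node_from_dict(doc: dict, depth: int, path: tuple, json_path: str):
    from .tree import TreeNode  # local import to avoid a cycle

    for key in ("feature", "p_value", "cells", "left", "right"):
        if key not in doc:
            raise ValueError(f"tree document missing {json_path}.{key}")
    feat = doc["feature"]
    feature = None if feat is None else AlterationFeature(feat["gene"], feat["type"])
    left = right = None
    if doc["left"] is not None:
        left = _node_from_dict(doc["left"], depth + 1,
                               path + ((feature, "altered"),),
                               json_path + ".left")
    if doc["right"] is not None:
        right = _node_from_dict(doc["right"], depth + 1,
                                path + ((feature, "wildtype"),),
                                json_path + ".right")
    return TreeNode(
        node_id=doc.get("node_id", json_path),
        cells=tuple(doc["cells"]),
        feature=feature,
        split_p=doc["p_value"],
        median_left=doc["median_canonical_left"],
        median_right=doc["median_canonical_right"],
        depth=depth,
        left=left,
        right=right,
        path=path,
    )


def write_tree(tree, path: str | Path) -> None:
    """Serialize a decision tree to JSON (full precision, round-trippable)."""
    doc = {
        "drug": tree.drug,
        "dataset": tree.dataset_name,
        "metric": None,
        "root": _node_to_dict(tree.root),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_tree(path: str | Path):
    from .tree import DecisionTree, TreeParams

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed tree JSON: {exc}") from exc
    for key in ("drug", "dataset", "root"):
        if key not in doc:
            raise ValueError(f"{path}: tree document missing $.{key}")
    root = _node_from_dict(doc["root"], depth=0, path=(), json_path="$.root")
    return DecisionTree(drug=doc["drug"], dataset_name=doc["dataset"],
                        root=root, params=TreeParams())
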