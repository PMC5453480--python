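"""Condition-labelled expression matrices and fold-change differential expression.

Expression is assumed pre-normalized on an RPKM-like non-negative scale
(depth- and length-corrected abundance); no count modelling or library-size
handling is done here. Differential expression uses the fold-change rule
FC > 2 or FC < 0.5, i.e. |log2 FC| > 1 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import normalize_id

CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Entities × samples of non-negative abundances plus condition labels.

    ``values`` is a DataFrame indexed by entity id with sample-id columns;
    ``condition_of`` maps every sample id to ``"normal"`` or ``"tumor"``.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated entity ids: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values are not allowed")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(
                f"samples missing from the condition map: {missing[:5]}"
            )
        bad = {
            s: c for s, c in self.condition_of.items()
            if s in self.values.columns and c not in CONDITIONS
        }
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def subset(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]

    def write_tsv(self, matrix_path: str | Path, condition_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="entity_id",
                           float_format="%.10g")
        if condition_path is not None:
            with open(condition_path, "w") as handle:
                for sample in self.values.columns:
                    handle.write(f"{sample}\t{self.condition_of[sample]}\n")


@dataclass
class DifferentialExpressionTable:
    """Per-entity condition means, log2 fold change and selection flag."""

    table: pd.DataFrame  # columns: mean_normal, mean_tumor, log2_fc, selected
    threshold: float | None = None

    @property
    def selected_ids(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])

    def log2_fc_of(self) -> dict[str, float]:
        return self.table["log2_fc"].to_dict()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="entity_id",
                          float_format="%.10g")


def load_expression(matrix_path: str | Path, condition_path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (entity rows, sample-id header) and condition map.

    Entity ids are lower-cased/stripped so they join the catalog namespace.
    Negative values, duplicated entity ids, and samples absent from the
    condition map are fatal.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = [normalize_id(str(e)) for e in values.index]
    values.columns = [str(c).strip() for c in values.columns]
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        raise ValueError(f"{matrix_path}: non-numeric expression values")
    condition_of: dict[str, str] = {}
    with open(condition_path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{condition_path}: malformed row {line!r}")
            condition_of[fields[0].strip()] = fields[1].strip().lower()
    return ExpressionMatrix(values=values.astype(float), condition_of=condition_of)


def compute_log2_fold_change(
    expr: ExpressionMatrix, pseudocount: float = 0.01
) -> DifferentialExpressionTable:
    """Per-entity log2((mean_tumor + c)/(mean_normal + c)) with pseudocount c.

    Means are arithmetic means over each condition's samples. The pseudocount
    (default 0.01, small on the RPKM scale) keeps zero-expression entities
    finite without materially shifting expressed ones.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    for condition in CONDITIONS:
        if len(expr.samples_of(condition)) == 0:
            raise ValueError(f"no samples with condition {condition!r}")
    mean_normal = expr.subset("normal").mean(axis=1)
    mean_tumor = expr.subset("tumor").mean(axis=1)
    log2_fc = np.log2((mean_tumor + pseudocount) / (mean_normal + pseudocount))
    table = pd.DataFrame(
        {
            "mean_normal": mean_normal,
            "mean_tumor": mean_tumor,
            "log2_fc": log2_fc,
            "selected": False,
        }
    )
    return DifferentialExpressionTable(table=table)


def select_differential(
    de_table: DifferentialExpressionTable, threshold: float = 1.0
) -> set[str]:
    """Entities with |log2 FC| strictly greater than ``threshold``.

    Strict inequality mirrors the FC > 2 or FC < 0.5 rule: an exact two-fold
    change is not called differential. Updates the table's ``selected``
    flags in place and returns the selected id set.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    selected = de_table.table["log2_fc"].abs() > threshold
    de_table.table["selected"] = selected
    de_table.threshold = threshold
    return set(de_table.table.index[selected])
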