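"""Cell-level quality control and library-size log-normalization.

Cells are dropped when they detect fewer than ``min_genes`` genes (empty
droplets / low-quality libraries), more than ``max_genes`` genes (likely
doublets), or when the mitochondrial fraction of their counts exceeds
``max_mito_frac`` (stressed or dying cells).  Boundary semantics follow the
strict inequalities of the rules: a cell with exactly ``min_genes`` detected
genes, exactly ``max_genes`` genes, or a mitochondrial fraction of exactly
``max_mito_frac`` is kept.

Downstream differential expression runs on library-size log-normalized
values: ``log(1 + count / cell_total * scale_factor)`` with a scale factor
of 10,000.  This replaces variance-stabilizing regression normalizations;
the decision is recorded in the QC report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import EmptyResultError, ValidationError
from .io import ExpressionMatrix

SCALE_FACTOR = 10_000.0


@dataclass
class QCThresholds:
    """QC rule thresholds; defaults are the standard 500 / 5,000 / 10% rules."""

    min_genes: int = 500
    max_genes: int = 5000
    max_mito_frac: float = 0.10
    mito_prefix: str = "MT-"
    mito_basis: str = "counts"  # "counts" (fraction of total counts) or "genes"

    def __post_init__(self):
        if not 0 < self.min_genes < self.max_genes:
            raise ValidationError("require 0 < min_genes < max_genes")
        if not 0 < self.max_mito_frac < 1:
            raise ValidationError("max_mito_frac must lie in (0, 1)")
        if self.mito_basis not in ("counts", "genes"):
            raise ValidationError("mito_basis must be 'counts' or 'genes'")


@dataclass
class QCReport:
    """Removed cells with the (first) rule each one failed, plus run metadata."""

    removed: pd.DataFrame  # columns: cell_id, reason
    thresholds: QCThresholds
    n_input: int
    n_kept: int
    metadata: dict = field(default_factory=dict)

    def counts_by_reason(self) -> dict[str, int]:
        return self.removed["reason"].value_counts().to_dict()

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.removed.to_csv(path, index=False)


def filter_cells(counts: ExpressionMatrix, thresholds: QCThresholds | None = None):
    """Drop QC-failing cells from a counts matrix.

    Returns ``(filtered, report)``.  A cell failing several rules is reported
    under the first failing rule in the fixed order low_genes -> high_genes ->
    high_mito (retention is unaffected by the attribution order).
    """
    thresholds = thresholds or QCThresholds()
    if counts.scale != "counts":
        raise ValidationError("filter_cells expects a counts-scale matrix")
    values = counts.values
    detected = (values > 0).sum(axis=0)
    mito_mask = np.array([g.startswith(thresholds.mito_prefix) for g in counts.gene_ids])
    totals = values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if thresholds.mito_basis == "counts":
            mito_frac = np.where(totals > 0, values[mito_mask].sum(axis=0) / np.maximum(totals, 1e-300), 0.0)
        else:
            mito_frac = np.where(detected > 0, (values[mito_mask] > 0).sum(axis=0) / np.maximum(detected, 1), 0.0)

    low = detected < thresholds.min_genes
    high = detected > thresholds.max_genes
    mito = mito_frac > thresholds.max_mito_frac
    fail = low | high | mito
    reason = np.full(counts.n_columns, "", dtype=object)
    reason[mito] = "high_mito"
    reason[high] = "high_genes"  # later assignments win: order low > high > mito
    reason[low] = "low_genes"

    removed = pd.DataFrame(
        {"cell_id": counts.column_ids[fail], "reason": reason[fail]}
    ).reset_index(drop=True)
    keep_idx = np.flatnonzero(~fail)
    if keep_idx.size == 0:
        raise EmptyResultError("all cells removed by QC")
    filtered = ExpressionMatrix(
        values[:, keep_idx], counts.gene_ids, counts.column_ids[keep_idx], scale="counts"
    )
    report = QCReport(
        removed=removed,
        thresholds=thresholds,
        n_input=counts.n_columns,
        n_kept=keep_idx.size,
        metadata={"normalization": "library-size log1p (scale 1e4); variance-stabilizing regression not applied"},
    )
    return filtered, report


def lognormalize(counts: ExpressionMatrix, scale_factor: float = SCALE_FACTOR) -> ExpressionMatrix:
    """``log(1 + count / cell_total * scale_factor)`` per cell (natural log)."""
    if counts.scale != "counts":
        raise ValidationError("lognormalize expects a counts-scale matrix")
    totals = counts.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValidationError("cell with zero total counts; run QC first")
    values = np.log1p(counts.values / totals * scale_factor)
    return ExpressionMatrix(values, counts.gene_ids, counts.column_ids, scale="normalized")


class CellQualityFilter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :func:`filter_cells`.

    ``fit`` evaluates the three QC rules on a counts :class:`ExpressionMatrix`
    and records the decision; ``transform`` drops the failing cells (and
    optionally log-normalizes).  Fitted attributes carry the usual trailing
    underscore.
    """

    def __init__(self, min_genes=500, max_genes=5000, max_mito_frac=0.10,
                 mito_prefix="MT-", mito_basis="counts", normalize=False):
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.max_mito_frac = max_mito_frac
        self.mito_prefix = mito_prefix
        self.mito_basis = mito_basis
        self.normalize = normalize

    def _thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_genes=self.min_genes,
            max_genes=self.max_genes,
            max_mito_frac=self.max_mito_frac,
            mito_prefix=self.mito_prefix,
            mito_basis=self.mito_basis,
        )

    def fit(self, X: ExpressionMatrix, y=None):
        if not isinstance(X, ExpressionMatrix):
            raise ValidationError("CellQualityFilter operates on ExpressionMatrix inputs")
        filtered, report = filter_cells(X, self._thresholds())
        self.report_ = report
        self.kept_cells_ = list(filtered.column_ids)
        self.n_removed_ = report.n_input - report.n_kept
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        filtered, _ = filter_cells(X, self._thresholds())
        return lognormalize(filtered) if self.normalize else filtered
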