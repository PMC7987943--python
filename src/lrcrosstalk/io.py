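"""Readers, writers and in-memory containers for every external format.

Expression matrices are genes x columns everywhere (columns are cells for
single-cell data and samples for bulk data).  Gene symbols are canonicalized
(upper-cased, whitespace-stripped) on ingest so that single-cell, bulk and
ligand-receptor tables can be joined by symbol; duplicate gene rows arising
from canonicalization are collapsed by summation for counts and by mean for
continuous scales.

On-disk formats
---------------
* dense TSV: header row = column ids, first column = gene id
* MatrixMarket ``.mtx`` with ``<stem>.genes.tsv`` / ``<stem>.cols.tsv`` sidecars
* CSV (RFC-4180, UTF-8) for the ligand-receptor table and clinical data
* JSON for fitted models and simulation truth
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_SCALES = ("counts", "normalized", "bulk")


def canonical_symbol(symbol: str) -> str:
    """Canonical gene symbol: upper-cased and whitespace-stripped."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """A nonnegative genes x columns expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_columns)
        Nonnegative, finite expression values.
    gene_ids : sequence of str
        Unique canonical gene symbols, one per row.
    column_ids : sequence of str
        Unique cell or sample identifiers, one per column.
    scale : {"counts", "normalized", "bulk"}
        What the values mean; drives duplicate-collapse and QC semantics.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    column_ids: np.ndarray
    scale: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray([canonical_symbol(g) for g in self.gene_ids], dtype=object)
        self.column_ids = np.asarray([str(c) for c in self.column_ids], dtype=object)
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("expression values must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids after canonicalization")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValidationError("duplicate column ids")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- accessors -----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene: str) -> bool:
        return canonical_symbol(gene) in self._gene_index

    def row(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across all columns."""
        key = canonical_symbol(gene)
        if key not in self._gene_index:
            raise KeyError(f"gene {gene!r} not present")
        return self.values[self._gene_index[key]]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[canonical_symbol(g)] for g in genes]
        return ExpressionMatrix(self.values[idx], self.gene_ids[idx], self.column_ids, self.scale)

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.column_ids)}
        missing = [c for c in columns if str(c) not in pos]
        if missing:
            raise ValidationError(f"unknown columns: {missing[:5]}")
        idx = [pos[str(c)] for c in columns]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, self.column_ids[idx], self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return collapse_duplicate_genes(
            df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns], scale
        )


def collapse_duplicate_genes(values, gene_ids, column_ids, scale) -> ExpressionMatrix:
    """Build an ExpressionMatrix, collapsing rows that share a canonical symbol.

    Counts are summed; continuous scales are averaged.  Row order follows the
    first occurrence of each symbol.
    """
    canon = [canonical_symbol(g) for g in gene_ids]
    values = np.asarray(values, dtype=float)
    if len(set(canon)) == len(canon):
        return ExpressionMatrix(values, canon, column_ids, scale)
    order: dict[str, list[int]] = {}
    for i, g in enumerate(canon):
        order.setdefault(g, []).append(i)
    reducer = np.sum if scale == "counts" else np.mean
    out = np.vstack([reducer(values[rows], axis=0) for rows in order.values()])
    logger.info("collapsed %d duplicate gene rows", len(canon) - len(order))
    return ExpressionMatrix(out, list(order), column_ids, scale)


@dataclass
class CellAnnotation:
    """Per-cell metadata: sample of origin, tumor/normal condition, cell type."""

    frame: pd.DataFrame  # columns: cell_id, sample_id, condition, cell_type

    REQUIRED = ("cell_id", "sample_id", "condition", "cell_type")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"cell annotation missing columns {missing}")
        bad = set(self.frame["condition"].unique()) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"condition must be tumor/normal, found {sorted(bad)}")
        if self.frame["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell ids in annotation")
        self.frame = self.frame.reset_index(drop=True)

    def subset(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        keep = self.frame[self.frame["cell_id"].isin(set(map(str, cell_ids)))]
        return CellAnnotation(keep.copy())

    def cells_of(self, cell_type: str, condition: str | None = None) -> list[str]:
        m = self.frame["cell_type"] == cell_type
        if condition is not None:
            m &= self.frame["condition"] == condition
        return self.frame.loc[m, "cell_id"].tolist()


@dataclass
class LigandReceptorDB:
    """Directed ligand -> receptor pair table.

    Pairs are ordered (never symmetrized: an arrow points from ligand to
    receptor) and deduplicated; homotypic pairs (ligand == receptor) are kept
    but flagged ``is_self``.
    """

    frame: pd.DataFrame  # columns: ligand, receptor, is_self [, source]

    def __post_init__(self):
        for col in ("ligand", "receptor"):
            if col not in self.frame.columns:
                raise FormatError(f"ligand-receptor table missing column {col!r}")
            self.frame[col] = self.frame[col].map(canonical_symbol)
        self.frame = self.frame.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)
        self.frame["is_self"] = self.frame["ligand"] == self.frame["receptor"]
        if self.frame.empty:
            logger.warning("ligand-receptor database is empty")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["ligand"], self.frame["receptor"]))

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        lig, rec = canonical_symbol(pair[0]), canonical_symbol(pair[1])
        return ((self.frame["ligand"] == lig) & (self.frame["receptor"] == rec)).any()

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]], source: str | None = None) -> "LigandReceptorDB":
        df = pd.DataFrame(pairs, columns=["ligand", "receptor"])
        if source is not None:
            df["source"] = source
        return cls(df)

    def merged(self, other: "LigandReceptorDB") -> "LigandReceptorDB":
        return LigandReceptorDB(
            pd.concat([self.frame, other.frame], ignore_index=True)[["ligand", "receptor"]]
        )


@dataclass
class SurvivalRecord:
    """One patient's time-to-event observation."""

    patient_id: str
    os_time: float
    os_event: int
    covariates: dict = field(default_factory=dict)
    true_lp: float | None = None  # simulation-only: the generating linear predictor
    time_unit: str = "years"

    def __post_init__(self):
        self.os_time = float(self.os_time)
        self.os_event = int(self.os_event)
        if self.os_time < 0:
            raise ValidationError(f"negative os_time for {self.patient_id}")
        if self.os_event not in (0, 1):
            raise ValidationError(f"os_event must be 0/1 for {self.patient_id}")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per patient, covariates as columns)."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "os_time": r.os_time, "os_event": r.os_event}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "tsv", scale: str = "counts") -> ExpressionMatrix:
    """Read a genes x columns expression matrix from TSV or MatrixMarket.

    For ``format="mtx"`` two sidecar files must exist next to the matrix:
    ``<stem>.genes.tsv`` (one gene id per line) and ``<stem>.cols.tsv``
    (one column id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values, genes, cols = df.to_numpy(dtype=float), list(df.index), list(df.columns)
    elif format == "mtx":
        genes_path = path.with_suffix(".genes.tsv")
        cols_path = path.with_suffix(".cols.tsv")
        for side in (genes_path, cols_path):
            if not side.exists():
                raise FormatError(f"missing MatrixMarket sidecar {side}")
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = genes_path.read_text().split()
        cols = cols_path.read_text().split()
        if values.shape != (len(genes), len(cols)):
            raise FormatError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cols)} columns)"
            )
    else:
        raise FormatError(f"unknown expression format {format!r}")
    if values.size and values.min() < 0:
        raise ValidationError(f"negative values in {path}")
    return collapse_duplicate_genes(values, genes, cols, scale)


def write_expression(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(matrix.values))
        path.with_suffix(".genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
        path.with_suffix(".cols.tsv").write_text("\n".join(matrix.column_ids) + "\n")
    else:
        raise FormatError(f"unknown expression format {format!r}")


def read_cell_annotation(path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, dtype=str))


def write_cell_annotation(annotation: CellAnnotation, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annotation.frame.to_csv(path, index=False)


def read_lr_db(path) -> LigandReceptorDB:
    """Read a ligand-receptor pair CSV (columns ``ligand``, ``receptor``)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"ligand-receptor CSV {path} missing column {col!r}")
    return LigandReceptorDB(df)


def bundled_lr_db() -> LigandReceptorDB:
    """The small curated ligand-receptor table shipped with the package."""
    return read_lr_db(Path(__file__).parent / "data" / "lr_pairs.csv")


def read_clinical(path, time_col="os_time", event_col="os_event", id_col="patient_id") -> list[SurvivalRecord]:
    """Read a clinical CSV into survival records.

    Rows with missing/non-numeric time or event, negative time, or a
    non-binary event flag are dropped; the count of dropped rows is logged
    together with per-row reasons at DEBUG level.
    """
    df = pd.read_csv(path)
    for col in (id_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"clinical CSV {path} missing column {col!r}")
    covar_cols = [c for c in df.columns if c not in (id_col, time_col, event_col)]
    records, dropped = [], []
    for i, row in df.iterrows():
        time = pd.to_numeric(row[time_col], errors="coerce")
        event = pd.to_numeric(row[event_col], errors="coerce")
        if pd.isna(time) or pd.isna(event):
            dropped.append((i, "non-numeric or missing time/event"))
            continue
        if time < 0:
            dropped.append((i, "negative os_time"))
            continue
        if int(event) not in (0, 1) or event != int(event):
            dropped.append((i, "event flag not 0/1"))
            continue
        covs = {c: row[c] for c in covar_cols if not pd.isna(row[c])}
        records.append(SurvivalRecord(str(row[id_col]), float(time), int(event), covs))
    if dropped:
        logger.warning("dropped %d of %d clinical rows", len(dropped), len(df))
        for i, reason in dropped:
            logger.debug("clinical row %d dropped: %s", i, reason)
    return records


def write_clinical(records: Sequence[SurvivalRecord], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def write_model(model, path) -> None:
    """Serialize any model object exposing ``to_dict`` to JSON (full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def read_model(path):
    """Round-trip counterpart of :func:`write_model`.

    Dispatches on the ``"kind"`` tag written by the model's ``to_dict``.
    """
    from . import model as model_mod  # local import to avoid a cycle

    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "lr_score":
        return model_mod.LRScoreModel.from_dict(payload)
    if kind == "ensemble":
        return model_mod.EnsembleModel.from_dict(payload)
    raise FormatError(f"unrecognized model kind {kind!r} in {path}")
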