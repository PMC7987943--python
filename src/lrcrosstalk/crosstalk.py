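"""Directed ligand-receptor crosstalk networks with bulk co-expression filtering.

Candidate edges come from differential expression: an L-R pair is a
candidate when its ligand and receptor are both significantly regulated in
the relevant cell types.  Autocrine candidates (ligand and receptor in the
same cell type) must be concordantly regulated and inherit that direction;
paracrine candidates require both genes up-regulated (ligand in the source
type, receptor in the target type).

Candidates are then validated in an independent bulk cohort: an edge is kept
only when the Spearman correlation of ligand and receptor expression across
the (optionally subset) bulk samples exceeds ``rho_min`` (default 0.3) with
a BH-adjusted p-value below ``alpha`` (default 0.05), BH taken across the
candidates of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult, bh_adjust, run_de
from .exceptions import StageError, ValidationError
from .io import CellAnnotation, ExpressionMatrix, LigandReceptorDB

logger = logging.getLogger(__name__)

MODES = ("autocrine", "paracrine_up")


@dataclass
class CandidatePair:
    ligand: str
    receptor: str
    source_cell_type: str
    target_cell_type: str
    regulation: str  # up | down


@dataclass
class CrosstalkPair:
    """A validated directed ligand -> receptor edge with its statistics."""

    ligand: str
    receptor: str
    source_cell_type: str
    target_cell_type: str
    regulation: str
    rho: float
    corr_p: float
    corr_adj_p: float


def map_pairs(
    ligand_de: Sequence[DEResult],
    receptor_de: Sequence[DEResult],
    db: LigandReceptorDB,
    mode: str,
    require_concordance: bool = True,
) -> list[CandidatePair]:
    """Map significance-filtered DE gene lists onto the L-R database.

    ``autocrine`` requires ligand and receptor significant in the same cell
    type with the same direction (the pair inherits it); ``paracrine_up``
    requires the ligand up in the source type and the receptor up in the
    target type.  ``require_concordance=False`` relaxes the autocrine rule,
    keeping discordant pairs with regulation tag ``"mixed"``.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    lig_dir = {r.gene: r.direction for r in ligand_de}
    rec_dir = {r.gene: r.direction for r in receptor_de}
    lig_ct = ligand_de[0].cell_type if ligand_de else ""
    rec_ct = receptor_de[0].cell_type if receptor_de else ""
    out = []
    for lig, rec in db.pairs:
        if lig not in lig_dir or rec not in rec_dir:
            continue
        if mode == "autocrine":
            if lig_dir[lig] != rec_dir[rec]:
                if require_concordance:
                    continue  # discordant regulation: excluded
                out.append(CandidatePair(lig, rec, lig_ct, rec_ct, "mixed"))
                continue
            out.append(CandidatePair(lig, rec, lig_ct, rec_ct, lig_dir[lig]))
        else:  # paracrine_up
            if lig_dir[lig] == "up" and rec_dir[rec] == "up":
                out.append(CandidatePair(lig, rec, lig_ct, rec_ct, "up"))
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]):
    """Spearman correlation: Pearson on mid-ranks, p from the t approximation.

    Ties receive average ranks.  Requires length >= 4 and non-constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValidationError("spearman_rho requires at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def cofilter(
    candidates: Sequence[CandidatePair],
    bulk: ExpressionMatrix,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    sample_subset: Sequence[str] | None = None,
) -> list[CrosstalkPair]:
    """Keep candidates co-expressed in bulk: rho > rho_min and BH-adjusted p < alpha.

    Candidates whose ligand or receptor is missing from the bulk matrix are
    dropped (bulk and single-cell gene universes routinely differ) with a
    logged count.  BH adjustment spans all surviving candidates of this call.
    """
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise ValidationError("sample_subset must not be empty")
        bulk = bulk.subset_columns(sample_subset)
    scored, dropped = [], 0
    for cand in candidates:
        if cand.ligand not in bulk or cand.receptor not in bulk:
            dropped += 1
            continue
        rho, p = spearman_rho(bulk.row(cand.ligand), bulk.row(cand.receptor))
        scored.append((cand, rho, p))
    if dropped:
        logger.info("cofilter: dropped %d candidates absent from bulk", dropped)
    if not scored:
        return []
    adj = bh_adjust([p for _, _, p in scored])
    return [
        CrosstalkPair(
            ligand=c.ligand,
            receptor=c.receptor,
            source_cell_type=c.source_cell_type,
            target_cell_type=c.target_cell_type,
            regulation=c.regulation,
            rho=float(rho),
            corr_p=float(p),
            corr_adj_p=float(q),
        )
        for (c, rho, p), q in zip(scored, adj)
        if rho > rho_min and q < alpha
    ]


def build_networks(
    sc_normalized: ExpressionMatrix,
    annotation: CellAnnotation,
    db: LigandReceptorDB,
    bulk: ExpressionMatrix,
    b_cell_type: str = "B",
    myeloid_cell_type: str = "MYELOID",
    de_alpha: float = 0.05,
    min_cells: int = 10,
    rho_min: float = 0.3,
    corr_alpha: float = 0.05,
    sample_subset: Sequence[str] | None = None,
) -> dict[str, list[CrosstalkPair]]:
    """Run DE + mapping + co-expression filtering for the three networks.

    Returns ``{"autocrine": ..., "b_to_myeloid": ..., "myeloid_to_b": ...}``.
    The autocrine network carries both up- and down-regulated edges (the
    ``regulation`` field distinguishes them); the two paracrine networks only
    consider up-regulated genes.  A pair may legitimately appear in more than
    one network.  Stage failures are re-raised tagged with the stage name.
    """
    try:
        b_de = run_de(sc_normalized, annotation, b_cell_type, alpha=de_alpha, min_cells=min_cells)
        m_de = run_de(sc_normalized, annotation, myeloid_cell_type, alpha=de_alpha, min_cells=min_cells)
    except Exception as exc:  # noqa: BLE001 - tag and re-raise
        raise StageError("differential_expression", exc) from exc

    try:
        plans = {
            "autocrine": map_pairs(b_de, b_de, db, "autocrine"),
            "b_to_myeloid": map_pairs(b_de, m_de, db, "paracrine_up"),
            "myeloid_to_b": map_pairs(m_de, b_de, db, "paracrine_up"),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("pair_mapping", exc) from exc

    networks = {}
    for name, candidates in plans.items():
        try:
            networks[name] = cofilter(
                candidates, bulk, rho_min=rho_min, alpha=corr_alpha, sample_subset=sample_subset
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"cofilter[{name}]", exc) from exc
    return networks


def network_frame(pairs: Sequence[CrosstalkPair]) -> pd.DataFrame:
    """Edge-list CSV layout for one network."""
    return pd.DataFrame(
        [
            {
                "ligand": p.ligand,
                "receptor": p.receptor,
                "source_cell_type": p.source_cell_type,
                "target_cell_type": p.target_cell_type,
                "regulation": p.regulation,
                "rho": p.rho,
                "corr_p": p.corr_p,
                "corr_adj_p": p.corr_adj_p,
            }
            for p in pairs
        ],
        columns=[
            "ligand", "receptor", "source_cell_type", "target_cell_type",
            "regulation", "rho", "corr_p", "corr_adj_p",
        ],
    )
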