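"""Tumor-vs-normal differential expression via a two-part hurdle test.

Single-cell expression is zero-inflated: whether a gene is detected at all
and how much is measured when detected carry separate information.  The
hurdle test therefore combines

* a *detection* part: a likelihood-ratio test of detection (expr > 0) on the
  group label under a Bernoulli/logistic model, and
* a *continuous* part: a likelihood-ratio test of the group effect on the
  log-normalized expression of the detected cells under a Gaussian linear
  model.

The two likelihood-ratio chi-squares are summed; degrees of freedom add, and
the p-value comes from the chi-square upper tail.  A degenerate part (all or
no cells detected for the detection part; fewer than two detected cells in a
group for the continuous part) contributes 0 with 0 df; if both parts are
degenerate the p-value is 1.  Multiple testing across the genes of one cell
type is controlled with Benjamini-Hochberg.

With a single binary covariate both likelihood-ratio statistics have closed
forms, which lets a whole matrix be tested in a few vectorized passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import CellAnnotation, ExpressionMatrix

_LN2 = np.log(2.0)


@dataclass
class DEResult:
    """One significant gene in one cell type."""

    gene: str
    cell_type: str
    log2fc: float
    p_value: float
    adj_p: float
    direction: str  # "up" | "down"


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bernoulli_ll(k, n):
    """Log-likelihood of k successes in n trials at the MLE rate (0 log 0 = 0)."""
    k, n = np.asarray(k, dtype=float), np.asarray(n, dtype=float)
    return special.xlogy(k, k / np.maximum(n, 1)) + special.xlogy(n - k, 1 - k / np.maximum(n, 1))


def hurdle_components(X: np.ndarray, is_tumor: np.ndarray):
    """Vectorized hurdle statistics for every row of a genes x cells matrix.

    Returns ``(chi2, df, p, log2fc)`` arrays.  ``log2fc`` is the difference of
    group means of the (natural-log) normalized values, rescaled to log2.
    """
    X = np.asarray(X, dtype=float)
    is_tumor = np.asarray(is_tumor, dtype=bool)
    n_t, n_n = int(is_tumor.sum()), int((~is_tumor).sum())
    if n_t < 2 or n_n < 2:
        raise ValidationError("hurdle test needs at least 2 cells per group")
    Xt, Xn = X[:, is_tumor], X[:, ~is_tumor]
    Dt, Dn = Xt > 0, Xn > 0
    kt, kn = Dt.sum(axis=1), Dn.sum(axis=1)

    # detection part: Bernoulli likelihood-ratio of group-specific vs pooled rates
    chi_det = 2.0 * (_bernoulli_ll(kt, n_t) + _bernoulli_ll(kn, n_n) - _bernoulli_ll(kt + kn, n_t + n_n))
    pooled = kt + kn
    df_det = np.where((pooled == 0) | (pooled == n_t + n_n), 0, 1)
    chi_det = np.where(df_det == 0, 0.0, np.maximum(chi_det, 0.0))

    # continuous part: Gaussian LRT on detected cells only
    st, sst = Xt.sum(axis=1), (Xt**2).sum(axis=1)
    sn, ssn = Xn.sum(axis=1), (Xn**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss_t = sst - st**2 / np.maximum(kt, 1)
        rss_n = ssn - sn**2 / np.maximum(kn, 1)
        rss1 = rss_t + rss_n
        k_all = kt + kn
        rss0 = (sst + ssn) - (st + sn) ** 2 / np.maximum(k_all, 1)
    df_cont = np.where((kt >= 2) & (kn >= 2), 1, 0)
    eps = 1e-12 * np.maximum(rss0, 1.0)
    degenerate_fit = rss0 <= eps  # detected values essentially constant
    df_cont = np.where(degenerate_fit, 0, df_cont)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi_cont = k_all * np.log(np.maximum(rss0, eps) / np.maximum(rss1, eps))
    chi_cont = np.where(df_cont == 0, 0.0, np.maximum(chi_cont, 0.0))

    chi2 = chi_det + chi_cont
    df = df_det + df_cont
    p = np.where(df > 0, stats.chi2.sf(chi2, np.maximum(df, 1)), 1.0)
    log2fc = (Xt.mean(axis=1) - Xn.mean(axis=1)) / _LN2
    return chi2, df, p, log2fc


def hurdle_test(expr: Sequence[float], is_tumor: Sequence[bool], covariates=None):
    """Two-part hurdle test for a single gene.

    Returns ``(statistic, p_value, log2fc)``; see module docstring for the
    model.  Constant expression across all cells yields ``(0, 1, 0)``.
    ``covariates`` is a reserved hook for nuisance adjustment (for example a
    cellular detection rate); only the unadjusted two-group test is
    currently implemented.
    """
    if covariates is not None:
        raise NotImplementedError("covariate adjustment is not implemented yet")
    expr = np.asarray(expr, dtype=float)[None, :]
    chi2, _, p, log2fc = hurdle_components(expr, np.asarray(is_tumor, dtype=bool))
    return float(chi2[0]), float(p[0]), float(log2fc[0])


def run_de(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    cell_type: str,
    alpha: float = 0.05,
    min_cells: int = 10,
) -> list[DEResult]:
    """Hurdle DE for one cell type; returns significant genes only.

    Genes detected in fewer than ``min_cells`` cells of the pooled tumor +
    normal population are not tested (degenerate fits).  BH adjustment runs
    across all tested genes of this cell type; results with adjusted p below
    ``alpha`` are returned split into up/down by the sign of the fold change.
    """
    meta = annotation.frame
    for condition in ("tumor", "normal"):
        if not ((meta["cell_type"] == cell_type) & (meta["condition"] == condition)).any():
            raise ValidationError(f"cell type {cell_type!r} absent in condition {condition!r}")
    cells = meta[meta["cell_type"] == cell_type]
    sub = matrix.subset_columns(cells["cell_id"].tolist())
    is_tumor = (cells["condition"] == "tumor").to_numpy()

    detected = (sub.values > 0).sum(axis=1)
    testable = np.flatnonzero(detected >= min_cells)
    if testable.size == 0:
        return []
    chi2, df, p, log2fc = hurdle_components(sub.values[testable], is_tumor)
    adj = bh_adjust(p)
    results = []
    for i, gi in enumerate(testable):
        if adj[i] < alpha:
            results.append(
                DEResult(
                    gene=str(sub.gene_ids[gi]),
                    cell_type=cell_type,
                    log2fc=float(log2fc[i]),
                    p_value=float(p[i]),
                    adj_p=float(adj[i]),
                    direction="up" if log2fc[i] > 0 else "down",
                )
            )
    return results


def de_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """Flatten DE results to the CSV layout (gene, cell_type, log2fc, p, adj_p, direction)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "cell_type": r.cell_type,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "adj_p": r.adj_p,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=["gene", "cell_type", "log2fc", "p_value", "adj_p", "direction"],
    )
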