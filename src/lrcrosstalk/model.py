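"""L1-penalized Cox regression, the leave-10%-out stability ensemble,
the LR score, and survival-tree dichotomization.

The prognostic model is built in three steps:

1.  **LASSO-Cox.**  ``cox_lasso`` minimizes the Breslow negative log partial
    likelihood plus ``lambda * sum |beta|`` by cyclic coordinate descent on
    the local quadratic approximation (IRLS outer loop, soft-thresholded
    coordinate updates inside), with covariates standardized internally and
    coefficients reported on the original scale.  KKT residuals are checked
    at convergence.

2.  **Stability ensemble.**  ``stability_ensemble`` repeats, for each of
    ``n_reps`` (default 1,000) replicates, a uniform leave-10%-out patient
    subsample, an inner cross-validated choice of lambda, and a LASSO-Cox
    fit.  A gene's *retention* is the number of replicates in which its
    coefficient is nonzero; genes retained in at least ``retention_threshold``
    (default 950) replicates enter the final model, whose coefficients are
    the averages over replicates (zeros included by default).

3.  **LR score and dichotomization.**  The LR score of a patient is the
    weighted sum of gene expression with the ensemble (or published)
    coefficients.  ``partition_cut`` scans all admissible score cutpoints for
    the one maximizing the log-rank chi-square, the single-split analog of a
    pruned survival tree.  Because the cutpoint is *selected* to maximize the
    statistic, the naive log-rank p is anticonservative; the pruning decision
    therefore uses the Lausen-Schumacher approximation for maximally selected
    rank statistics, while the naive p of the chosen split is also reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, ValidationError
from .io import SurvivalRecord, canonical_symbol
from .survival import logrank_test as _logrank_exact

logger = logging.getLogger(__name__)

_PUBLISHED_MODEL_PATH = Path(__file__).parent / "data" / "lr_score_model.json"


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery
# ---------------------------------------------------------------------------

def _sort_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    idx = np.arange(n)
    is_new = np.ones(n, dtype=bool)
    is_new[1:] = t[1:] != t[:-1]
    # first index of each subject's tie group (starts are increasing, so a
    # running max over "start index or 0" recovers them)
    group_start = np.maximum.accumulate(np.where(is_new, idx, 0))
    is_end = np.ones(n, dtype=bool)
    is_end[:-1] = t[1:] != t[:-1]
    group_end = np.minimum.accumulate(np.where(is_end, idx, n - 1)[::-1])[::-1]
    return order, t, e, group_start, group_end


def _breslow_quantities(e, group_start, group_end, eta):
    """Negative log partial likelihood, per-subject gradient and curvature.

    Subjects are assumed sorted ascending in time.  Returns
    ``(nll, g, w)`` with ``g`` the gradient of the *log-likelihood* with
    respect to eta and ``w`` the (diagonal) negative curvature.
    """
    ex = np.exp(eta - eta.max())  # stabilized; constants cancel in all ratios
    suffix = np.cumsum(ex[::-1])[::-1]
    S = suffix[group_start]  # risk-set sum at each subject's event time
    log_S = np.log(S) + eta.max()
    nll = -(np.sum(eta[e == 1]) - np.sum(log_S[e == 1]))

    inv = np.where(e == 1, 1.0 / S, 0.0)
    inv2 = np.where(e == 1, 1.0 / S**2, 0.0)
    A = np.cumsum(inv)[group_end]      # sum over event times <= t_i of 1/S
    B = np.cumsum(inv2)[group_end]
    g = e - ex * A
    w = ex * A - ex**2 * B
    return nll, g, w


def _penalized_objective(e, group_start, group_end, Xs, beta, lam):
    eta = Xs @ beta
    nll, _, _ = _breslow_quantities(e, group_start, group_end, eta)
    return nll + lam * np.abs(beta).sum()


def _soft(x, lam):
    return np.sign(x) * max(abs(x) - lam, 0.0)


def _cd_wls_numpy(Xs, wX, w, z, lam, beta, denom, tol, max_pass):
    """Cyclic coordinate descent on the weighted LASSO subproblem (pure numpy)."""
    r = z - Xs @ beta
    p = beta.size
    for _ in range(max_pass):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho_j = wX[:, j] @ r + denom[j] * bj
            new = _soft(rho_j, lam) / denom[j]
            if new != bj:
                r -= Xs[:, j] * (new - bj)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        if max_delta < tol:
            break
    return beta


try:  # the jitted kernel is a drop-in speedup; the numpy path is authoritative
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _cd_wls_kernel(Xs, w, z, lam, beta, denom, tol, max_pass):  # pragma: no cover
        n, p = Xs.shape
        r = z - Xs @ beta
        for _ in range(max_pass):
            max_delta = 0.0
            for j in range(p):
                bj = beta[j]
                s = 0.0
                for i in range(n):
                    s += w[i] * Xs[i, j] * r[i]
                rho_j = s + denom[j] * bj
                if rho_j > lam:
                    new = (rho_j - lam) / denom[j]
                elif rho_j < -lam:
                    new = (rho_j + lam) / denom[j]
                else:
                    new = 0.0
                if new != bj:
                    d = new - bj
                    for i in range(n):
                        r[i] -= Xs[i, j] * d
                    beta[j] = new
                    if abs(d) > max_delta:
                        max_delta = abs(d)
            if max_delta < tol:
                break
        return beta

    _HAVE_NUMBA = True
except Exception:  # noqa: BLE001
    _HAVE_NUMBA = False


def _cd_wls(Xs, w, z, lam, beta, denom, active_only, tol=1e-12, max_pass=1000):  # noqa: PLR0913
    """One weighted-least-squares LASSO solve by cyclic coordinate descent."""
    if _HAVE_NUMBA:
        return _cd_wls_kernel(
            np.ascontiguousarray(Xs), w, z, float(lam), beta, denom, float(tol), max_pass
        )
    return _cd_wls_numpy(Xs, Xs * w[:, None], w, z, lam, beta, denom, tol, max_pass)


def _fit_cox_lasso_std(e, group_start, group_end, Xs, lam, beta0=None,
                       max_outer=200, outer_tol=1e-10, inner_tol=1e-12):
    """LASSO-Cox on pre-standardized covariates; returns (beta, n_iter, kkt)."""
    n, p = Xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    obj = _penalized_objective(e, group_start, group_end, Xs, beta, lam)
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        eta = Xs @ beta
        _, g, w = _breslow_quantities(e, group_start, group_end, eta)
        w = np.maximum(w, 1e-9)
        z = eta + g / w
        denom = (w[:, None] * Xs**2).sum(axis=0)
        denom = np.maximum(denom, 1e-12)
        new_beta = _cd_wls(Xs, w, z, lam, beta.copy(), denom, active_only=p > 20, tol=inner_tol)
        step = new_beta - beta
        # safeguard: backtrack if the quadratic model overshot
        new_obj = _penalized_objective(e, group_start, group_end, Xs, beta + step, lam)
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 20:
            step *= 0.5
            new_obj = _penalized_objective(e, group_start, group_end, Xs, beta + step, lam)
            halvings += 1
        beta = beta + step
        delta = np.abs(step).max() if step.size else 0.0
        obj = new_obj
        if delta < outer_tol:
            break
    else:
        raise ConvergenceError(
            f"cox_lasso did not converge in {max_outer} outer iterations (last delta {delta:.2e})"
        )
    beta[np.abs(beta) < 1e-12] = 0.0  # snap numerically-zero coordinates
    # KKT residuals: grad of nll wrt beta_j is -Xs[:,j] @ g
    _, g, _ = _breslow_quantities(e, group_start, group_end, Xs @ beta)
    grad = -(Xs.T @ g)
    kkt = np.where(beta == 0, np.maximum(np.abs(grad) - lam, 0.0), np.abs(grad + lam * np.sign(beta)))
    return beta, n_iter, float(kkt.max()) if kkt.size else 0.0


def _standardize(X):
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("constant covariate; cannot standardize")
    return (X - mean) / sd, mean, sd


def lambda_max(time, event, X) -> float:
    """Smallest penalty at which the LASSO-Cox solution is exactly zero.

    Equal to the max absolute gradient of the null model on the
    standardized-covariate scale.
    """
    order, t, e, gs, ge = _sort_survival(time, event)
    Xs, _, _ = _standardize(np.asarray(X, dtype=float)[order])
    _, g, _ = _breslow_quantities(e, gs, ge, np.zeros(t.size))
    return float(np.abs(Xs.T @ g).max())


@dataclass
class LassoFit:
    """One penalized Cox solution."""

    lam: float
    coefficients: dict[str, float]  # original covariate scale; sparse (zeros included)
    n_iter: int
    kkt_residual: float
    objective: float  # penalized objective on the standardized scale

    @property
    def support(self) -> list[str]:
        return [g for g, b in self.coefficients.items() if b != 0.0]


def _fit_arrays(time, event, X, lam, names, beta0=None, outer_tol=1e-10, inner_tol=1e-12):
    order, t, e, gs, ge = _sort_survival(time, event)
    if e.sum() < 1:
        raise ValidationError("LASSO-Cox needs at least one event")
    Xs, _, sd = _standardize(np.asarray(X, dtype=float)[order])
    beta_std, n_iter, kkt = _fit_cox_lasso_std(
        e, gs, ge, Xs, lam, beta0=beta0, outer_tol=outer_tol, inner_tol=inner_tol
    )
    obj = _penalized_objective(e, gs, ge, Xs, beta_std, lam)
    coefs = {name: float(b / s) for name, b, s in zip(names, beta_std, sd)}
    return LassoFit(float(lam), coefs, n_iter, kkt, float(obj)), beta_std


def cox_lasso(records: Sequence[SurvivalRecord], covariates: pd.DataFrame, lam: float) -> LassoFit:
    """Fit an L1-penalized Cox model at a single penalty value.

    ``covariates`` is a numeric DataFrame indexed by patient id.  Covariates
    are standardized internally; the returned coefficients apply to the
    original scale.
    """
    if lam < 0:
        raise ValidationError("lambda must be nonnegative")
    t = np.array([r.os_time for r in records])
    e = np.array([r.os_event for r in records])
    X = covariates.loc[[r.patient_id for r in records]].to_numpy(dtype=float)
    fit, _ = _fit_arrays(t, e, X, lam, list(covariates.columns))
    return fit


# ---------------------------------------------------------------------------
# cross-validated lambda
# ---------------------------------------------------------------------------

def _path_fit(time, event, X, grid, outer_tol=1e-6, inner_tol=1e-8):
    """Warm-started fits down a descending lambda grid (standardized betas).

    CV paths only rank lambdas, so they run at loose tolerances; the final
    reported fit is always re-solved tightly.
    """
    order, t, e, gs, ge = _sort_survival(time, event)
    Xs, mean, sd = _standardize(np.asarray(X, dtype=float)[order])
    betas = []
    beta = np.zeros(Xs.shape[1])
    for lam in grid:
        beta, _, _ = _fit_cox_lasso_std(
            e, gs, ge, Xs, lam, beta0=beta, outer_tol=outer_tol, inner_tol=inner_tol
        )
        betas.append(beta.copy())
    return betas, mean, sd


def lambda_grid(time, event, X, n_lambda: int = 30, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending grid from lambda_max down two decades."""
    lmax = lambda_max(time, event, X)
    if lmax == 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def select_lambda(time, event, X, k: int = 10, grid=None, n_lambda: int = 30,
                  min_ratio: float = 0.01, random_state=None, rule: str = "1se") -> float:
    """Pick lambda by k-fold cross-validated partial-likelihood deviance.

    Deviance uses the Verweij-van Houwelingen cross-validated partial
    likelihood: for each fold, ``-2 * (ll_full(beta_-k) - ll_train(beta_-k))``.
    ``rule="min"`` returns the deviance-minimizing lambda; ``rule="1se"``
    (default) returns the heaviest penalty whose mean deviance is within one
    standard error of the minimum -- the parsimony rule stability selection
    needs, since chance dataset-level correlations otherwise keep noise
    covariates in nearly every 90% subsample.  A fold with zero events
    triggers one reshuffle; a second failure raises.
    """
    if rule not in ("min", "1se"):
        raise ValidationError("rule must be 'min' or '1se'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    n = time.size
    if k < 2:
        raise ValidationError("k-fold CV requires k >= 2")
    if grid is None:
        grid = lambda_grid(time, event, X, n_lambda=n_lambda, min_ratio=min_ratio)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 1:
        return float(grid[0])

    rng = np.random.default_rng(random_state)
    for attempt in range(2):
        folds = np.array_split(rng.permutation(n), k)
        if all(event[f].sum() > 0 for f in folds):
            break
        if attempt == 1:
            raise ValidationError("a CV fold has zero events even after reshuffling")

    # sort the full cohort once; per-fold training data is sorted inside _path_fit
    order_all, _, e_all, gs_all, ge_all = _sort_survival(time, event)
    X_all_sorted = X[order_all]
    dev = np.zeros((len(folds), grid.size))
    for f, fold in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        betas, mean, sd = _path_fit(time[mask], event[mask], X[mask], grid)
        order_tr, _, e_tr, gs_tr, ge_tr = _sort_survival(time[mask], event[mask])
        Xs_tr = (X[mask][order_tr] - mean) / sd
        Xs_full = (X_all_sorted - mean) / sd
        for i, beta in enumerate(betas):
            nll_train, _, _ = _breslow_quantities(e_tr, gs_tr, ge_tr, Xs_tr @ beta)
            nll_full, _, _ = _breslow_quantities(e_all, gs_all, ge_all, Xs_full @ beta)
            # Verweij-van Houwelingen: -2 * (ll_full - ll_train)
            dev[f, i] += -2.0 * (nll_train - nll_full)
    mean_dev = dev.mean(axis=0)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        return float(grid[i_min])
    se = dev.std(axis=0, ddof=1)[i_min] / np.sqrt(len(folds))
    within = np.flatnonzero(mean_dev <= mean_dev[i_min] + se)
    return float(grid[int(within[0])])  # grid descends: first index = heaviest penalty


# ---------------------------------------------------------------------------
# stability ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Retention counts and averaged coefficients from the resampling LASSO."""

    genes: list[str]
    retention: dict[str, int]
    avg_coef: dict[str, float]
    n_reps: int = 1000
    subsample_frac: float = 0.9
    retention_threshold: int = 950
    seed: int | None = None
    average: str = "all"  # "all": zeros included; "selected": over selecting reps only
    n_failed: int = 0

    @property
    def final_genes(self) -> list[str]:
        return [g for g in self.genes if self.retention[g] >= self.retention_threshold]

    def to_lr_model(self) -> "LRScoreModel":
        coefs = {g: self.avg_coef[g] for g in self.final_genes}
        return LRScoreModel(coefficients=coefs, provenance="fitted")

    def to_dict(self) -> dict:
        return {
            "kind": "ensemble",
            "genes": self.genes,
            "retention": self.retention,
            "avg_coef": self.avg_coef,
            "n_reps": self.n_reps,
            "subsample_frac": self.subsample_frac,
            "retention_threshold": self.retention_threshold,
            "seed": self.seed,
            "average": self.average,
            "n_failed": self.n_failed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EnsembleModel":
        payload = {k: v for k, v in payload.items() if k != "kind"}
        return cls(**payload)


def stability_ensemble(
    records: Sequence[SurvivalRecord],
    covariates: pd.DataFrame,
    n_reps: int = 1000,
    frac: float = 0.9,
    threshold: int = 950,
    seed: int | None = None,
    cv_folds: int = 10,
    n_lambda: int = 30,
    average: str = "all",
    lambda_rule: str = "1se",
) -> EnsembleModel:
    """Leave-(1-frac)-out LASSO-Cox stability ensemble.

    Each replicate subsamples ``frac`` of the patients without replacement,
    selects lambda by inner ``cv_folds``-fold CV, fits, and records the
    coefficient vector.  Retention counts nonzero coefficients per gene;
    averaged coefficients include the zero estimates unless
    ``average="selected"``.  More than 5% failed replicates aborts the run.
    """
    t = np.array([r.os_time for r in records], dtype=float)
    e = np.array([r.os_event for r in records], dtype=int)
    X = covariates.loc[[r.patient_id for r in records]].to_numpy(dtype=float)
    names = list(covariates.columns)
    n = t.size
    m = int(np.floor(frac * n))
    if m < 2:
        raise ValidationError("subsample too small")
    if average not in ("all", "selected"):
        raise ValidationError("average must be 'all' or 'selected'")

    children = np.random.SeedSequence(seed).spawn(n_reps)
    coef_matrix = np.zeros((n_reps, len(names)))
    selected = np.zeros((n_reps, len(names)), dtype=bool)
    failed = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep])
        idx = rng.choice(n, size=m, replace=False)
        try:
            if e[idx].sum() < 1:
                raise ValidationError("subsample without events")
            lam = select_lambda(t[idx], e[idx], X[idx], k=cv_folds, n_lambda=n_lambda,
                                random_state=rng, rule=lambda_rule)
            fit, _ = _fit_arrays(t[idx], e[idx], X[idx], lam, names,
                                 outer_tol=1e-8, inner_tol=1e-10)
        except Exception as exc:  # noqa: BLE001 - per-replicate failures are tallied
            failed += 1
            logger.debug("ensemble replicate %d failed: %r", rep, exc)
            if failed > 0.05 * n_reps:
                raise ConvergenceError(f"more than 5% of replicates failed ({failed}/{rep + 1})") from exc
            continue
        vec = np.array([fit.coefficients[g] for g in names])
        coef_matrix[rep] = vec
        selected[rep] = vec != 0

    n_ok = n_reps - failed
    retention = {g: int(selected[:, j].sum()) for j, g in enumerate(names)}
    if average == "all":
        avg = coef_matrix.sum(axis=0) / max(n_ok, 1)
    else:
        counts = np.maximum(selected.sum(axis=0), 1)
        avg = coef_matrix.sum(axis=0) / counts
    avg_coef = {g: float(avg[j]) if retention[g] else 0.0 for j, g in enumerate(names)}
    return EnsembleModel(
        genes=names,
        retention=retention,
        avg_coef=avg_coef,
        n_reps=n_reps,
        subsample_frac=frac,
        retention_threshold=threshold,
        seed=seed,
        average=average,
        n_failed=failed,
    )


# ---------------------------------------------------------------------------
# LR score
# ---------------------------------------------------------------------------

@dataclass
class LRScoreModel:
    """A linear gene-expression risk score: sum of coefficient * expression."""

    coefficients: dict[str, float]
    provenance: str = "fitted"  # "paper" | "fitted"
    expression_scale: str = "unspecified"

    def __post_init__(self):
        if not self.coefficients:
            raise ValidationError("LR score model must have at least one gene")
        self.coefficients = {canonical_symbol(g): float(b) for g, b in self.coefficients.items()}

    def score(self, expression: Mapping[str, float]) -> float:
        return lr_score(self, expression)

    def score_columns(self, bulk) -> pd.Series:
        """LR score per column of an ExpressionMatrix; missing genes contribute 0."""
        values = np.zeros(bulk.n_columns)
        missing = []
        for g, b in self.coefficients.items():
            if g in bulk:
                values += b * bulk.row(g)
            else:
                missing.append(g)
        if missing:
            logger.warning("LR score: %d model genes absent from matrix: %s", len(missing), missing)
        return pd.Series(values, index=bulk.column_ids, name="lr_score")

    def to_dict(self) -> dict:
        return {
            "kind": "lr_score",
            "coefficients": self.coefficients,
            "provenance": self.provenance,
            "expression_scale": self.expression_scale,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LRScoreModel":
        payload = {k: v for k, v in payload.items() if k != "kind"}
        return cls(**payload)


def lr_score(model: LRScoreModel, expression: Mapping[str, float]) -> float:
    """Weighted sum of expression; genes absent from the map contribute 0."""
    expr = {canonical_symbol(g): float(v) for g, v in expression.items()}
    missing = [g for g in model.coefficients if g not in expr]
    if missing:
        logger.warning("LR score: genes absent from expression map: %s", missing)
    return float(sum(b * expr.get(g, 0.0) for g, b in model.coefficients.items()))


def published_model() -> LRScoreModel:
    """The packaged 11-gene LR-score model with its printed coefficients."""
    payload = json.loads(_PUBLISHED_MODEL_PATH.read_text())
    return LRScoreModel.from_dict(payload)


# ---------------------------------------------------------------------------
# survival-tree dichotomization
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    """Outcome of the optimal single-split search on a score."""

    significant: bool
    cutpoint: float | None
    labels: np.ndarray | None  # "high" where score > cutpoint
    chi2: float
    p: float  # naive log-rank p of the chosen split
    p_adjusted: float  # selection-adjusted (maximally selected statistic)
    n_low: int
    n_high: int


def _logrank_chi2_fast(t_sorted, e_sorted, high_sorted):
    """Log-rank chi-square (hypergeometric variance) for one binary split."""
    n = t_sorted.size
    # unique event times with counts, walking ascending
    U = 0.0
    V = 0.0
    i = 0
    n_at_risk = n
    n1_suffix = np.concatenate([np.cumsum(high_sorted[::-1])[::-1], [0]])
    while i < n:
        j = i
        d = d1 = 0
        while j < n and t_sorted[j] == t_sorted[i]:
            if e_sorted[j]:
                d += 1
                d1 += int(high_sorted[j])
            j += 1
        if d > 0:
            n_risk = n - i
            n1 = n1_suffix[i]
            frac = n1 / n_risk
            U += d1 - d * frac
            if n_risk > 1:
                V += d * frac * (1 - frac) * (n_risk - d) / (n_risk - 1)
        i = j
    return (U * U / V) if V > 0 else 0.0


def _lausen_schumacher_p(b: float, eps_low: float, eps_high: float) -> float:
    """Approximate p-value for a maximally selected standardized statistic.

    ``b`` is the observed max |standardized log-rank statistic| and
    ``(eps_low, eps_high)`` the quantile window scanned.
    """
    if b <= 1.0:
        return 1.0
    phi = stats.norm.pdf(b)
    log_term = np.log((eps_high * (1 - eps_low)) / (eps_low * (1 - eps_high)))
    p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
    return float(min(max(p, 2.0 * stats.norm.sf(b)), 1.0))


def partition_cut(
    scores: Sequence[float],
    records: Sequence[SurvivalRecord],
    min_frac: float = 0.1,
    alpha: float = 0.05,
) -> SplitResult:
    """Optimal log-rank dichotomization of a score with a pruning rule.

    Scans the midpoints of consecutive sorted unique scores whose resulting
    groups both contain at least ``min_frac`` of the cohort, and returns the
    cutpoint maximizing the log-rank chi-square.  The split is retained only
    if the selection-adjusted p-value (Lausen-Schumacher approximation for
    maximally selected rank statistics) is below ``alpha``; otherwise a null
    result is returned -- the analog of pruning the one-split survival tree.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(records):
        raise ValidationError("scores must align with records")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValidationError("need at least 2 distinct scores to split")
    n = scores.size
    floor = min_frac * n

    t = np.array([r.os_time for r in records], dtype=float)
    e = np.array([r.os_event for r in records], dtype=int)
    order = np.argsort(t, kind="stable")
    t_sorted, e_sorted = t[order], e[order]
    scores_sorted_by_time = scores[order]

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_high_per_mid = np.array([(scores > c).sum() for c in mids])
    admissible = (n_high_per_mid >= floor) & ((n - n_high_per_mid) >= floor)
    if not admissible.any():
        raise ValidationError("no admissible cutpoint under the minimum group-size floor")

    best_chi2, best_cut = -1.0, None
    for c in mids[admissible]:
        chi2 = _logrank_chi2_fast(t_sorted, e_sorted, scores_sorted_by_time > c)
        if chi2 > best_chi2:
            best_chi2, best_cut = chi2, float(c)

    labels = np.where(scores > best_cut, "high", "low")
    chi2, p = _logrank_exact(list(records), labels)
    p_adj = _lausen_schumacher_p(np.sqrt(max(chi2, 0.0)), min_frac, 1.0 - min_frac)
    n_high = int((labels == "high").sum())
    if p_adj >= alpha:
        return SplitResult(False, None, None, float(chi2), float(p), p_adj, n - n_high, n_high)
    return SplitResult(True, best_cut, labels, float(chi2), float(p), p_adj, n - n_high, n_high)


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

def _extract_surv_y(y):
    """Accept a sksurv structured array, an (n, 2) array, or a DataFrame."""
    if isinstance(y, pd.DataFrame):
        return y["os_time"].to_numpy(dtype=float), y["os_event"].to_numpy(dtype=int)
    y = np.asarray(y)
    if y.dtype.names:  # structured: boolean/int event field + time field
        names = list(y.dtype.names)
        event_field = names[0] if y.dtype[names[0]].kind in "b?i" else names[1]
        time_field = names[1] if event_field == names[0] else names[0]
        return y[time_field].astype(float), y[event_field].astype(int)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(int)
    raise ValidationError("y must be a structured survival array, (n,2) [time,event], or DataFrame")


def _extract_X(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    return X, [f"x{j}" for j in range(X.shape[1])]


class CoxLasso(BaseEstimator):
    """L1-penalized Cox proportional-hazards regression.

    Parameters
    ----------
    alpha : float
        The L1 penalty (on the standardized-covariate scale of the Breslow
        negative log partial likelihood).
    """

    def __init__(self, alpha: float = 0.0):
        self.alpha = alpha

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        Xv, names = _extract_X(X)
        t, e = _extract_surv_y(y)
        fit, _ = _fit_arrays(t, e, Xv, self.alpha, names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.coef_ = np.array([fit.coefficients[g] for g in names])
        self.fit_ = fit
        self.n_iter_ = fit.n_iter
        return self

    def predict(self, X):
        """Linear risk predictor on the original covariate scale."""
        Xv, _ = _extract_X(X)
        return Xv @ self.coef_


class StabilityCoxLasso(BaseEstimator):
    """The leave-10%-out LASSO-Cox stability-selection ensemble.

    ``fit`` runs :func:`stability_ensemble`; ``predict`` returns the LR score
    under the final averaged coefficients (genes below the retention
    threshold contribute nothing).
    """

    def __init__(self, n_reps=1000, subsample_frac=0.9, retention_threshold=950,
                 cv_folds=10, n_lambda=30, average="all", random_state=None):
        self.n_reps = n_reps
        self.subsample_frac = subsample_frac
        self.retention_threshold = retention_threshold
        self.cv_folds = cv_folds
        self.n_lambda = n_lambda
        self.average = average
        self.random_state = random_state

    def fit(self, X, y):
        Xv, names = _extract_X(X)
        t, e = _extract_surv_y(y)
        ids = [f"s{i}" for i in range(Xv.shape[0])]
        records = [SurvivalRecord(pid, ti, ei) for pid, ti, ei in zip(ids, t, e)]
        cov = pd.DataFrame(Xv, index=ids, columns=names)
        self.ensemble_ = stability_ensemble(
            records, cov,
            n_reps=self.n_reps, frac=self.subsample_frac,
            threshold=self.retention_threshold, seed=self.random_state,
            cv_folds=self.cv_folds, n_lambda=self.n_lambda, average=self.average,
        )
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.retention_ = np.array([self.ensemble_.retention[g] for g in names])
        self.coef_ = np.array([
            self.ensemble_.avg_coef[g] if g in self.ensemble_.final_genes else 0.0 for g in names
        ])
        self.support_ = self.retention_ >= self.retention_threshold
        return self

    def predict(self, X):
        Xv, _ = _extract_X(X)
        return Xv @ self.coef_

    def to_model(self) -> LRScoreModel:
        return self.ensemble_.to_lr_model()


class SurvivalTreeCut(BaseEstimator):
    """Single-split survival tree: optimal log-rank cutpoint on a 1-d score."""

    def __init__(self, min_frac: float = 0.1, alpha: float = 0.05):
        self.min_frac = min_frac
        self.alpha = alpha

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).reshape(-1)
        t, e = _extract_surv_y(y)
        records = [SurvivalRecord(f"s{i}", ti, ei) for i, (ti, ei) in enumerate(zip(t, e))]
        self.split_ = partition_cut(scores, records, min_frac=self.min_frac, alpha=self.alpha)
        self.cutpoint_ = self.split_.cutpoint
        return self

    def predict(self, X):
        if self.cutpoint_ is None:
            raise ValidationError("no significant split was found; cannot assign groups")
        scores = np.asarray(X, dtype=float).reshape(-1)
        return np.where(scores > self.cutpoint_, "high", "low")
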