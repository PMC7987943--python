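"""Kaplan-Meier estimation, log-rank testing and Cox proportional-hazards fits.

Thin, validated wrappers over lifelines that return the plain containers the
rest of the pipeline consumes.  Cox fits use Efron's approximation for tied
event times and report hazard ratios with 1.96-SE Wald confidence intervals
plus the likelihood-ratio p-value of the whole model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import ValidationError
from .io import ExpressionMatrix, SurvivalRecord


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct observed times."""

    times: np.ndarray  # ascending
    survival: np.ndarray  # S(t), starts at 1, nonincreasing
    at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("KM times must be ascending")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("KM survival must be nonincreasing")
        if self.survival.size and not (0 <= self.survival.min() and self.survival.max() <= 1):
            raise ValidationError("KM survival must lie in [0, 1]")

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "at_risk": self.at_risk})


@dataclass
class CoxFit:
    """A fitted proportional-hazards model summary."""

    coefficients: dict[str, float]
    hr: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]  # per-covariate Wald
    lr_p: float  # likelihood-ratio p of the whole model
    converged: bool
    log_likelihood: float = float("nan")
    n: int = 0
    n_events: int = 0
    diagnostics: str = ""

    def summary_frame(self) -> pd.DataFrame:
        """Forest-plot style table: covariate, HR, CI, p."""
        rows = [
            {
                "covariate": k,
                "coef": self.coefficients[k],
                "HR": self.hr[k],
                "ci_lower": self.ci_lower[k],
                "ci_upper": self.ci_upper[k],
                "p": self.p_values[k],
            }
            for k in self.coefficients
        ]
        return pd.DataFrame(rows, columns=["covariate", "coef", "HR", "ci_lower", "ci_upper", "p"])


def _records_arrays(records: Sequence[SurvivalRecord]):
    if len(records) == 0:
        raise ValidationError("need at least one survival record")
    t = np.array([r.os_time for r in records], dtype=float)
    e = np.array([r.os_event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over the records.

    Subjects censored exactly at an event time count as at risk for that
    time (the standard convention; lifelines follows it).
    """
    t, e = _records_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    keep = times > 0  # drop the implicit t=0 anchor; S(0)=1 by construction
    ev = kmf.event_table
    return KMCurve(times[keep], sf.to_numpy(dtype=float)[keep], ev["at_risk"].to_numpy(dtype=float)[keep])


def logrank_test(records: Sequence[SurvivalRecord], groups: Sequence) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi2, p)`` with 1 df."""
    groups = np.asarray(groups)
    if len(groups) != len(records):
        raise ValidationError("group labels must align with records")
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"log-rank requires exactly 2 nonempty groups, got {len(labels)}")
    t, e = _records_arrays(records)
    m = groups == labels[0]
    res = _ll_logrank(t[m], t[~m], e[m], e[~m])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(records: Sequence[SurvivalRecord], covariates: pd.DataFrame) -> CoxFit:
    """Multivariable Cox PH fit (Efron ties) of the given covariates.

    ``covariates`` is indexed by patient id; categorical columns are one-hot
    encoded with the first level as reference.  Non-convergence and monotone
    likelihood (perfect separation) are reported on the returned fit rather
    than raised, matching the ``converged`` invariant downstream code checks.
    """
    t, e = _records_arrays(records)
    if e.sum() < 1:
        raise ValidationError("Cox fit needs at least one event")
    ids = [r.patient_id for r in records]
    missing = [i for i in ids if i not in covariates.index]
    if missing:
        raise ValidationError(f"covariates missing for patients {missing[:5]}")
    X = covariates.loc[ids].copy()
    cat = X.select_dtypes(exclude=[np.number]).columns
    if len(cat):
        X = pd.get_dummies(X, columns=list(cat), drop_first=True, dtype=float)
    df = X.reset_index(drop=True)
    df["os_time"], df["os_event"] = t, e

    cph = CoxPHFitter()
    diagnostics = ""
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="os_time", event_col="os_event")
        for w in caught:
            msg = str(w.message)
            if "complete separation" in msg or "monotone" in msg or "convergence" in msg.lower():
                converged = False
                diagnostics = msg
    except LLConvergenceError as exc:
        return CoxFit({}, {}, {}, {}, {}, float("nan"), converged=False,
                      n=len(records), n_events=int(e.sum()), diagnostics=str(exc))

    summ = cph.summary
    return CoxFit(
        coefficients=summ["coef"].to_dict(),
        hr=summ["exp(coef)"].to_dict(),
        ci_lower=np.exp(summ["coef"] - 1.96 * summ["se(coef)"]).to_dict(),
        ci_upper=np.exp(summ["coef"] + 1.96 * summ["se(coef)"]).to_dict(),
        p_values=summ["p"].to_dict(),
        lr_p=float(cph.log_likelihood_ratio_test().p_value),
        converged=converged,
        log_likelihood=float(cph.log_likelihood_),
        n=len(records),
        n_events=int(e.sum()),
        diagnostics=diagnostics,
    )


def split_by_mean(bulk: ExpressionMatrix, gene: str, records: Sequence[SurvivalRecord]):
    """Dichotomize patients at the mean expression of one gene.

    The high group is expression >= mean (values exactly at the mean go
    high).  Returns ``(labels, (chi2, p), (km_high, km_low))`` where labels
    align with ``records``.
    """
    matched = [r for r in records if str(r.patient_id) in set(bulk.column_ids)]
    if not matched:
        raise ValidationError("no records match bulk sample ids")
    expr = bulk.subset_columns([r.patient_id for r in matched]).row(gene)
    if np.ptp(expr) == 0:
        raise ValidationError(f"gene {gene!r} has constant expression; cannot split")
    labels = np.where(expr >= expr.mean(), "high", "low")
    if len(pd.unique(labels)) < 2:
        raise ValidationError(f"mean split of {gene!r} produced a single group")
    chi2, p = logrank_test(matched, labels)
    km_high = km_estimate([r for r, g in zip(matched, labels) if g == "high"])
    km_low = km_estimate([r for r, g in zip(matched, labels) if g == "low"])
    return labels, (chi2, p), (km_high, km_low)
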