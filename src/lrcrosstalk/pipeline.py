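"""End-to-end orchestration: simulate -> QC -> DE -> crosstalk -> model -> evaluate.

``run_all`` executes the enabled stages in order, persists every intermediate
artifact under the output directory, and returns a machine-readable report.
All randomness flows from the single root seed, fanned out to per-stage
substreams, so a rerun with the same configuration is byte-identical
(timings go to the log, never into the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .crosstalk import build_networks, network_frame
from .exceptions import StageError, ValidationError
from .io import (
    ExpressionMatrix,
    SurvivalRecord,
    read_cell_annotation,
    read_clinical,
    read_expression,
    read_lr_db,
    write_model,
)
from .model import LRScoreModel, partition_cut, stability_ensemble
from .simulate import simulate_crosstalk_study, write_study
from .survival import cox_fit, km_estimate, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Threshold defaults are the pipeline's reference settings: QC at 500 /
    5,000 detected genes and 10% mitochondrial counts, DE and correlation
    alpha 0.05, correlation floor 0.3, ensemble of 1,000 leave-10%-out
    replicates with a 950-replicate retention threshold.
    """

    outdir: str = "lrcrosstalk_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_qc: bool = True
    run_crosstalk: bool = True
    run_model: bool = True
    run_evaluate: bool = True
    # input paths (used when simulate=False)
    sc_counts: str | None = None
    sc_format: str = "mtx"
    cell_annotation: str | None = None
    bulk: str | None = None
    clinical: str | None = None
    lr_db: str | None = None
    sample_subset: Sequence[str] | None = None
    # thresholds (reference defaults)
    min_genes: int = 500
    max_genes: int = 5000
    max_mito_frac: float = 0.10
    de_alpha: float = 0.05
    min_cells: int = 10
    rho_min: float = 0.3
    corr_alpha: float = 0.05
    n_reps: int = 1000
    subsample_frac: float = 0.9
    retention_threshold: int = 950
    cv_folds: int = 10
    split_min_frac: float = 0.1
    split_alpha: float = 0.05
    # cohort handling
    b_cell_type: str = "B"
    myeloid_cell_type: str = "MYELOID"
    validation_frac: float = 0.3
    transfer_cutpoint: bool = True
    covariates: Sequence[str] = field(default_factory=lambda: ["gender", "risk_group"])
    model_genes: Sequence[str] | None = None  # used when crosstalk stage is off
    simulate_params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def validate_model(
    model: LRScoreModel,
    bulk: ExpressionMatrix,
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str] = (),
    cutpoint: float | None = None,
    min_frac: float = 0.1,
    alpha: float = 0.05,
) -> dict:
    """Evaluate an LR-score model on a cohort.

    Computes per-patient scores, dichotomizes (at a supplied training
    cutpoint, or by re-deriving the optimal cutpoint on this cohort when
    ``cutpoint`` is None), and reports Kaplan-Meier curves, the log-rank
    test, and univariable plus (when covariates are given) multivariable Cox
    fits of the high-vs-low indicator.
    """
    present = [g for g in model.coefficients if g in bulk]
    if not present:
        raise ValidationError("no model genes present in the expression matrix")
    matched = [r for r in records if str(r.patient_id) in set(bulk.column_ids)]
    if not matched:
        raise ValidationError("no clinical records match expression columns")
    scores = model.score_columns(bulk.subset_columns([r.patient_id for r in matched]))

    out: dict = {
        "n": len(matched),
        "n_model_genes": len(model.coefficients),
        "n_genes_present": len(present),
    }
    if cutpoint is None:
        split = partition_cut(scores.to_numpy(), matched, min_frac=min_frac, alpha=alpha)
        out["cutpoint_source"] = "rederived"
        out["split_p_adjusted"] = split.p_adjusted
        if not split.significant:
            out.update(significant_split=False, cutpoint=None)
            return out
        cut = split.cutpoint
    else:
        cut = float(cutpoint)
        out["cutpoint_source"] = "transferred"
    labels = np.where(scores.to_numpy() > cut, "high", "low")
    if len(pd.unique(labels)) < 2:
        out.update(significant_split=False, cutpoint=cut, note="single group at this cutpoint")
        return out
    chi2, p = logrank_test(matched, labels)
    out.update(
        significant_split=bool(p < alpha),
        cutpoint=cut,
        logrank_chi2=float(chi2),
        logrank_p=float(p),
        n_high=int((labels == "high").sum()),
        n_low=int((labels == "low").sum()),
    )

    cov = pd.DataFrame({"high_score": (labels == "high").astype(float)},
                       index=[r.patient_id for r in matched])
    uni = cox_fit(matched, cov)
    out["univariable"] = _cox_table(uni)
    if covariates:
        frame = pd.DataFrame(
            {c: [r.covariates.get(c) for r in matched] for c in covariates},
            index=[r.patient_id for r in matched],
        )
        multi = cox_fit(matched, pd.concat([cov, frame], axis=1))
        out["multivariable"] = _cox_table(multi)
    km = {
        g: km_estimate([r for r, lab in zip(matched, labels) if lab == g]).to_frame().to_dict("list")
        for g in ("high", "low")
    }
    out["km"] = km
    return out


def _cox_table(fit) -> list[dict]:
    return [
        {
            "covariate": k,
            "HR": fit.hr[k],
            "ci_lower": fit.ci_lower[k],
            "ci_upper": fit.ci_upper[k],
            "p": fit.p_values[k],
        }
        for k in fit.coefficients
    ]


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and return (and persist) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    report: dict = {"seed": config.seed, "stages": []}

    # ---- inputs ----------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        params = dict(config.simulate_params)
        params.setdefault("surv_beta", {"RCBM01": 0.9, "RCBM02": -0.85, "LGAU01": 0.8})
        study = simulate_crosstalk_study(seed=int(seeds[0].generate_state(1)[0] % 2**31), **params)
        write_study(study, outdir / "data")
        return study

    if config.simulate:
        study = _simulate()
        counts, annotation = study.counts, study.annotation
        bulk, records, db = study.bulk, study.records, study.lr_db
        report["stages"].append("simulate")
        report["simulate"] = {
            "n_cells": counts.n_columns,
            "n_genes": counts.n_genes,
            "n_bulk_samples": bulk.n_columns,
            "n_true_pairs": len(study.truth.true_pairs),
        }
    else:
        if not (config.sc_counts and config.cell_annotation and config.bulk and config.lr_db):
            raise StageError("inputs", ValidationError("simulate=False requires input paths"))
        counts = read_expression(config.sc_counts, format=config.sc_format, scale="counts")
        annotation = read_cell_annotation(config.cell_annotation)
        bulk = read_expression(config.bulk, format="tsv", scale="bulk")
        records = read_clinical(config.clinical) if config.clinical else []
        db = read_lr_db(config.lr_db)

    # ---- QC --------------------------------------------------------------
    @_stage("qc")
    def _qc():
        thresholds = qc_mod.QCThresholds(
            min_genes=config.min_genes,
            max_genes=config.max_genes,
            max_mito_frac=config.max_mito_frac,
        )
        filtered, qc_report = qc_mod.filter_cells(counts, thresholds)
        qc_report.write(outdir / "qc_report.csv")
        return qc_mod.lognormalize(filtered), qc_report

    if config.run_qc:
        normalized, qc_report = _qc()
        annotation = annotation.subset(normalized.column_ids)
        report["stages"].append("qc")
        report["qc"] = {
            "n_input_cells": qc_report.n_input,
            "n_kept_cells": qc_report.n_kept,
            "removed_by_reason": dict(sorted(qc_report.counts_by_reason().items())),
        }
    else:
        normalized = qc_mod.lognormalize(counts) if counts.scale == "counts" else counts

    # ---- crosstalk (includes DE) ----------------------------------------
    model_genes: list[str]
    if config.run_crosstalk:

        @_stage("crosstalk")
        def _crosstalk():
            networks = build_networks(
                normalized,
                annotation,
                db,
                bulk,
                b_cell_type=config.b_cell_type,
                myeloid_cell_type=config.myeloid_cell_type,
                de_alpha=config.de_alpha,
                min_cells=config.min_cells,
                rho_min=config.rho_min,
                corr_alpha=config.corr_alpha,
                sample_subset=list(config.sample_subset) if config.sample_subset else None,
            )
            for name, pairs in networks.items():
                network_frame(pairs).to_csv(outdir / f"network_{name}.csv", index=False)
            return networks

        networks = _crosstalk()
        report["stages"].append("crosstalk")
        report["crosstalk"] = {
            name: {
                "n_pairs": len(pairs),
                "pairs": sorted(f"{p.ligand}->{p.receptor}" for p in pairs),
            }
            for name, pairs in networks.items()
        }
        genes = set()
        for pairs in networks.values():
            for p in pairs:
                genes.update((p.ligand, p.receptor))
        model_genes = sorted(g for g in genes if g in bulk)
    else:
        if not config.model_genes:
            raise StageError("model", ValidationError("crosstalk disabled: provide model_genes"))
        model_genes = sorted(g for g in config.model_genes if g in bulk)

    # ---- model -----------------------------------------------------------
    if config.run_model:
        if not records:
            raise StageError("model", ValidationError("no clinical records available"))
        if not model_genes:
            raise StageError("model", ValidationError("no candidate genes present in bulk"))

        @_stage("model")
        def _model():
            rng = np.random.default_rng(seeds[1])
            ids = np.array([r.patient_id for r in records])
            perm = rng.permutation(len(ids))
            n_val = int(np.floor(config.validation_frac * len(ids)))
            val_ids = set(ids[perm[:n_val]])
            train = [r for r in records if r.patient_id not in val_ids]
            val = [r for r in records if r.patient_id in val_ids]
            cov = bulk.subset_genes(model_genes).to_frame().T  # samples x genes
            ensemble = stability_ensemble(
                train,
                cov,
                n_reps=config.n_reps,
                frac=config.subsample_frac,
                threshold=config.retention_threshold,
                seed=int(seeds[2].generate_state(1)[0] % 2**31),
                cv_folds=config.cv_folds,
            )
            write_model(ensemble, outdir / "ensemble.json")
            lr_model = ensemble.to_lr_model() if ensemble.final_genes else None
            if lr_model is not None:
                write_model(lr_model, outdir / "lr_score_model.json")
            return ensemble, lr_model, train, val

        ensemble, lr_model, train, val = _model()
        report["stages"].append("model")
        report["model"] = {
            "n_candidate_genes": len(model_genes),
            "n_train": len(train),
            "n_validation": len(val),
            "n_reps": ensemble.n_reps,
            "retention_threshold": ensemble.retention_threshold,
            "final_genes": ensemble.final_genes,
            "avg_coefficients": {g: ensemble.avg_coef[g] for g in ensemble.final_genes},
            "n_failed_replicates": ensemble.n_failed,
        }
    else:
        lr_model, train, val = None, [], []

    # ---- evaluate --------------------------------------------------------
    if config.run_evaluate and lr_model is not None:

        @_stage("evaluate")
        def _evaluate():
            train_scores = lr_model.score_columns(
                bulk.subset_columns([r.patient_id for r in train])
            )
            split = partition_cut(
                train_scores.to_numpy(), train,
                min_frac=config.split_min_frac, alpha=config.split_alpha,
            )
            cut = split.cutpoint if (split.significant and config.transfer_cutpoint) else None
            evaluation = validate_model(
                lr_model,
                bulk,
                val,
                covariates=list(config.covariates),
                cutpoint=cut,
                min_frac=config.split_min_frac,
                alpha=config.split_alpha,
            )
            return split, evaluation

        split, evaluation = _evaluate()
        report["stages"].append("evaluate")
        report["evaluate"] = {
            "train_split": {
                "significant": split.significant,
                "cutpoint": split.cutpoint,
                "chi2": split.chi2,
                "p": split.p,
                "p_adjusted": split.p_adjusted,
                "n_low": split.n_low,
                "n_high": split.n_high,
            },
            "validation": evaluation,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    config.to_json(outdir / "config.json")
    return report
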