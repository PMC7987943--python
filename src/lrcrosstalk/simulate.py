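"""Synthetic single-cell / bulk / survival data with planted ground truth.

The generators emulate the statistical structure the analysis pipeline
assumes, at desk scale:

* single-cell counts: negative-binomial per gene and cell, with tumor-vs-
  normal log2 fold changes planted on designated (gene, cell type) entries,
  and cells deliberately planted to violate each of the three QC rules;
* bulk expression: log-normal marginals with pairwise Spearman correlation
  planted through a Gaussian copula (the Gaussian correlation ``r`` that
  yields a target Spearman ``rho`` is ``r = 2 sin(pi * rho / 6)``);
* survival: exponential proportional-hazards times driven by a known linear
  predictor over standardized bulk expression, with independent censoring.

Everything is reproducible from ``SimConfig.seed``; the three generators use
disjoint deterministic substreams so they can be called in any order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import (
    CellAnnotation,
    ExpressionMatrix,
    LigandReceptorDB,
    SurvivalRecord,
    canonical_symbol,
    write_cell_annotation,
    write_clinical,
    write_expression,
)

_MITO_NAMES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]


def default_gene_names(n_genes: int, n_mito_genes: int, named: Sequence[str] = ()) -> list[str]:
    """Mitochondrial names first, then caller-supplied names, then autonames."""
    if n_mito_genes > n_genes:
        raise ConfigurationError("n_mito_genes exceeds n_genes")
    mito = [_MITO_NAMES[i] if i < len(_MITO_NAMES) else f"MT-G{i + 1}" for i in range(n_mito_genes)]
    named = [canonical_symbol(g) for g in named]
    n_auto = n_genes - n_mito_genes - len(named)
    if n_auto < 0:
        raise ConfigurationError("more named genes than available non-mitochondrial slots")
    taken = set(mito) | set(named)
    auto, i = [], 0
    while len(auto) < n_auto:
        i += 1
        candidate = f"G{i:05d}"
        if candidate not in taken:
            auto.append(candidate)
    names = mito + named + auto
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate gene names in simulation config")
    return names


@dataclass
class SimConfig:
    """Parameters of the simulated world.

    Defaults mirror the study design the pipeline targets: 7 tumor and 4
    normal single-cell samples, a bulk cohort of 300 samples (the scale at
    which the co-expression filter operates), 20% censoring.  Cell counts
    per sample and the gene panel are desk-scale.
    """

    n_genes: int = 2000
    n_mito_genes: int = 13
    cell_types: Mapping[str, int] = field(default_factory=lambda: {"B": 120, "MYELOID": 80, "T": 80})
    n_tumor_samples: int = 7
    n_normal_samples: int = 4
    de_plan: Sequence[tuple[str, str, float]] = ()  # (gene, cell_type, log2 fold change)
    nb_dispersion: float = 0.5
    base_mean_range: tuple[float, float] = (0.1, 4.0)
    # genes named in de_plan draw their base mean from this range instead
    # (ligands/receptors under study are expressed genes); None = same range
    planted_base_mean_range: tuple[float, float] | None = None
    n_bulk_samples: int = 300
    corr_plan: Sequence[tuple[str, str, float]] = ()  # (gene_a, gene_b, Spearman rho)
    surv_beta: Mapping[str, float] = field(default_factory=dict)
    censor_rate: float = 0.2
    baseline_hazard: float = 0.1
    seed: int = 0
    gene_names: Sequence[str] | None = None
    # planted QC violations: counts of cells breaking each rule, and the
    # thresholds the planting is calibrated against
    qc_fail_plan: tuple[int, int, int] = (0, 0, 0)  # (low_genes, high_genes, high_mito)
    qc_min_genes: int = 500
    qc_max_genes: int = 5000
    qc_max_mito_frac: float = 0.10

    def __post_init__(self):
        for name in ("n_genes", "n_mito_genes", "n_tumor_samples", "n_normal_samples", "n_bulk_samples"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not self.cell_types or any(n <= 0 for n in self.cell_types.values()):
            raise ConfigurationError("cell_types must map names to positive per-sample counts")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ConfigurationError("base_mean_range must be a positive interval")
        if self.planted_base_mean_range is not None:
            plo, phi = self.planted_base_mean_range
            if not (0 < plo <= phi):
                raise ConfigurationError("planted_base_mean_range must be a positive interval")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        for a, b, rho in self.corr_plan:
            if not abs(rho) <= 0.99:
                raise ConfigurationError(
                    f"planted Spearman rho for ({a}, {b}) outside supported range |rho| <= 0.99"
                )
        seen: dict[tuple[str, str], float] = {}
        for a, b, rho in self.corr_plan:
            key = tuple(sorted((canonical_symbol(a), canonical_symbol(b))))
            if key in seen and seen[key] != rho:
                raise ConfigurationError(f"contradictory corr_plan entries for pair {key}")
            seen[key] = rho
        if any(n < 0 for n in self.qc_fail_plan):
            raise ConfigurationError("qc_fail_plan counts must be nonnegative")

    def resolved_gene_names(self) -> list[str]:
        if self.gene_names is not None:
            names = [canonical_symbol(g) for g in self.gene_names]
            if len(names) != self.n_genes or len(set(names)) != len(names):
                raise ConfigurationError("gene_names must be n_genes unique symbols")
            return names
        planned = []
        for g, _, _ in self.de_plan:
            planned.append(g)
        for a, b, _ in self.corr_plan:
            planned.extend([a, b])
        planned.extend(self.surv_beta)
        uniq = list(dict.fromkeys(canonical_symbol(g) for g in planned))
        return default_gene_names(self.n_genes, self.n_mito_genes, uniq)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside each simulated dataset."""

    de_genes: set[tuple[str, str, str]] = field(default_factory=set)  # (gene, cell_type, up/down)
    true_pairs: set[tuple[str, str, str]] = field(default_factory=set)  # (ligand, receptor, network)
    surv_beta: dict[str, float] = field(default_factory=dict)
    qc_fail_cells: dict[str, str] = field(default_factory=dict)  # cell_id -> reason

    def to_dict(self) -> dict:
        return {
            "de_genes": sorted(self.de_genes),
            "true_pairs": sorted(self.true_pairs),
            "surv_beta": dict(sorted(self.surv_beta.items())),
            "qc_fail_cells": dict(sorted(self.qc_fail_cells.items())),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _nb_counts(rng, mean, dispersion):
    """Negative-binomial draws with mean ``mean`` and size ``dispersion``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def generate_sc(config: SimConfig):
    """Simulate single-cell counts, annotation and ground truth.

    Returns ``(counts, annotation, truth)``.  Counts are genes x cells; the
    tumor condition shifts the negative-binomial mean of each ``de_plan``
    entry by ``2**lfc`` for cells of the planned cell type.  QC-violating
    cells (if any are planned) are appended after the regular cells and
    recorded in ``truth.qc_fail_cells``.
    """
    rng = np.random.default_rng([config.seed, 11])
    names = config.resolved_gene_names()
    name_index = {g: i for i, g in enumerate(names)}
    is_mito = np.array([g.startswith("MT-") for g in names])

    known_types = set(config.cell_types)
    de_by_type: dict[str, list[tuple[int, float]]] = {}
    truth = SyntheticTruth(surv_beta={canonical_symbol(g): float(b) for g, b in config.surv_beta.items()})
    for gene, cell_type, lfc in config.de_plan:
        gene = canonical_symbol(gene)
        if gene not in name_index:
            raise ConfigurationError(f"de_plan references unknown gene {gene!r}")
        if cell_type not in known_types:
            raise ConfigurationError(f"de_plan references unknown cell type {cell_type!r}")
        de_by_type.setdefault(cell_type, []).append((name_index[gene], float(lfc)))
        if lfc != 0:
            truth.de_genes.add((gene, cell_type, "up" if lfc > 0 else "down"))

    lo, hi = config.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    if config.planted_base_mean_range is not None:
        plo, phi = config.planted_base_mean_range
        planted = sorted({name_index[canonical_symbol(g)] for g, _, _ in config.de_plan})
        base_mean[planted] = np.exp(rng.uniform(np.log(plo), np.log(phi), size=len(planted)))

    samples = [(f"T{i + 1}", "tumor") for i in range(config.n_tumor_samples)] + [
        (f"N{i + 1}", "normal") for i in range(config.n_normal_samples)
    ]
    blocks, meta = [], []
    for sample_id, condition in samples:
        for cell_type, n_cells in config.cell_types.items():
            mu = base_mean.copy()
            if condition == "tumor":
                for gi, lfc in de_by_type.get(cell_type, []):
                    mu[gi] = mu[gi] * 2.0 ** lfc
            block = _nb_counts(rng, np.broadcast_to(mu[:, None], (config.n_genes, n_cells)), config.nb_dispersion)
            blocks.append(block)
            meta.extend(
                (f"{sample_id}_{cell_type}_{k + 1}", sample_id, condition, cell_type)
                for k in range(n_cells)
            )
    counts = np.concatenate(blocks, axis=1)

    # planted QC violators, appended after the regular cells
    n_low, n_high, n_mito_fail = config.qc_fail_plan
    if n_low or n_high or n_mito_fail:
        nonmito_idx = np.flatnonzero(~is_mito)
        mito_idx = np.flatnonzero(is_mito)
        if n_low and config.qc_min_genes - 100 > len(nonmito_idx):
            raise ConfigurationError("too few non-mitochondrial genes to plant low-gene cells")
        if n_high and config.qc_max_genes + 100 > len(nonmito_idx):
            raise ConfigurationError(
                "planting high-gene violators requires n_genes > qc_max_genes + 100 + n_mito_genes"
            )
        plant_sample, plant_condition = samples[0]
        plant_type = next(iter(config.cell_types))
        extra, extra_meta = [], []

        def fresh_cell():
            return _nb_counts(rng, base_mean, config.nb_dispersion)

        for k in range(n_low):  # keep exactly min_genes - 100 detected, all non-mito
            cell = np.zeros(config.n_genes)
            keep = nonmito_idx[: config.qc_min_genes - 100]
            cell[keep] = np.maximum(fresh_cell()[keep], 1.0)
            cid = f"QCLOW_{k + 1}"
            extra.append(cell)
            extra_meta.append((cid, plant_sample, plant_condition, plant_type))
            truth.qc_fail_cells[cid] = "low_genes"
        for k in range(n_high):  # force > max_genes detected genes
            cell = fresh_cell()
            boost = nonmito_idx[: config.qc_max_genes + 100]
            cell[boost] = cell[boost] + 1.0
            cell[mito_idx] = 0.0
            cid = f"QCHIGH_{k + 1}"
            extra.append(cell)
            extra_meta.append((cid, plant_sample, plant_condition, plant_type))
            truth.qc_fail_cells[cid] = "high_genes"
        for k in range(n_mito_fail):  # push mito count fraction to ~0.30
            cell = fresh_cell()
            cell[mito_idx] = 0.0
            nonmito_total = cell.sum()
            per_gene = np.ceil(nonmito_total * (0.3 / 0.7) / max(len(mito_idx), 1))
            cell[mito_idx] = per_gene
            cid = f"QCMITO_{k + 1}"
            extra.append(cell)
            extra_meta.append((cid, plant_sample, plant_condition, plant_type))
            truth.qc_fail_cells[cid] = "high_mito"
        counts = np.concatenate([counts, np.column_stack(extra)], axis=1)
        meta.extend(extra_meta)

    annotation = CellAnnotation(pd.DataFrame(meta, columns=["cell_id", "sample_id", "condition", "cell_type"]))
    matrix = ExpressionMatrix(counts, names, annotation.frame["cell_id"], scale="counts")
    return matrix, annotation, truth


def _correlation_components(corr_plan, name_index):
    """Connected components of the planted-correlation graph."""
    adj: dict[int, dict[int, float]] = {}
    for a, b, rho in corr_plan:
        ia, ib = name_index[canonical_symbol(a)], name_index[canonical_symbol(b)]
        if ia == ib:
            raise ConfigurationError(f"corr_plan pairs a gene with itself: {a}")
        adj.setdefault(ia, {})[ib] = rho
        adj.setdefault(ib, {})[ia] = rho
    seen, components = set(), []
    for start in adj:
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        components.append((sorted(comp), adj))
    return components


def generate_bulk(config: SimConfig, truth: SyntheticTruth | None = None) -> ExpressionMatrix:
    """Simulate a bulk cohort with planted pairwise Spearman correlations.

    Marginals are log-normal (a monotone transform of Gaussian latents, so the
    rank-based planted correlation is preserved exactly in population).
    """
    rng = np.random.default_rng([config.seed, 13])
    names = config.resolved_gene_names()
    name_index = {g: i for i, g in enumerate(names)}
    for a, b, _ in config.corr_plan:
        for g in (a, b):
            if canonical_symbol(g) not in name_index:
                raise ConfigurationError(f"corr_plan references unknown gene {g!r}")

    n = config.n_bulk_samples
    latent = rng.standard_normal((config.n_genes, n))
    for comp, adj in _correlation_components(config.corr_plan, name_index):
        k = len(comp)
        pos = {g: i for i, g in enumerate(comp)}
        corr = np.eye(k)
        for gi in comp:
            for gj, rho in adj[gi].items():
                r = 2.0 * np.sin(np.pi * rho / 6.0)  # Gaussian corr for target Spearman
                corr[pos[gi], pos[gj]] = corr[pos[gj], pos[gi]] = r
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                f"corr_plan component {sorted(names[g] for g in comp)} is not jointly realizable"
            ) from exc
        latent[comp, :] = chol @ rng.standard_normal((k, n))

    lo, hi = config.base_mean_range
    log_mean = rng.uniform(np.log(lo), np.log(hi), size=config.n_genes)
    values = np.exp(log_mean[:, None] + latent)
    columns = [f"P{i + 1:04d}" for i in range(n)]
    return ExpressionMatrix(values, names, columns, scale="bulk")


def generate_survival(config: SimConfig, bulk: ExpressionMatrix) -> list[SurvivalRecord]:
    """Simulate exponential proportional-hazards survival on bulk expression.

    The hazard for patient ``i`` is ``h0 * exp(sum_g beta_g z_gi)`` with
    ``z_g`` the standardized bulk expression of gene ``g``.  Censoring is an
    independent exponential calibrated so a baseline subject is censored with
    probability ``censor_rate``; a negligible deterministic jitter breaks ties.
    """
    rng = np.random.default_rng([config.seed, 17])
    beta = {canonical_symbol(g): float(b) for g, b in config.surv_beta.items()}
    for g in beta:
        if g not in bulk:
            raise ConfigurationError(f"surv_beta references gene {g!r} absent from bulk matrix")

    n = bulk.n_columns
    lp = np.zeros(n)
    for g, b in beta.items():
        x = bulk.row(g)
        sd = x.std()
        if sd == 0:
            raise ConfigurationError(f"gene {g!r} has constant bulk expression")
        lp += b * (x - x.mean()) / sd

    h0 = config.baseline_hazard
    event_time = rng.exponential(1.0 / (h0 * np.exp(lp)))
    cr = config.censor_rate
    if cr >= 1.0:
        censor_time = np.zeros(n)
    elif cr <= 0.0:
        censor_time = np.full(n, np.inf)
    else:
        lam_c = h0 * cr / (1.0 - cr)
        censor_time = rng.exponential(1.0 / lam_c, size=n)

    gender = rng.choice(["male", "female"], size=n)
    risk = rng.choice(["low", "intermediate", "high"], size=n, p=[0.4, 0.4, 0.2])
    records = []
    for i, pid in enumerate(bulk.column_ids):
        t = min(event_time[i], censor_time[i]) + (i + 1) * 1e-9  # deterministic tie-breaking jitter
        records.append(
            SurvivalRecord(
                patient_id=str(pid),
                os_time=t,
                os_event=int(event_time[i] <= censor_time[i]),
                covariates={"gender": gender[i], "risk_group": risk[i]},
                true_lp=float(lp[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# linked crosstalk scenario
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """A linked single-cell + bulk + survival world with its truth and L-R table."""

    config: SimConfig
    counts: ExpressionMatrix
    annotation: CellAnnotation
    bulk: ExpressionMatrix
    records: list[SurvivalRecord]
    truth: SyntheticTruth
    lr_db: LigandReceptorDB


def simulate_crosstalk_study(
    n_autocrine_up: int = 4,
    n_autocrine_down: int = 3,
    n_b_to_myeloid: int = 4,
    n_myeloid_to_b: int = 3,
    n_decoys: int = 10,
    lfc: float = 1.5,
    rho: float = 0.6,
    planted_base_mean_range: tuple[float, float] = (2.0, 5.0),
    surv_beta: Mapping[str, float] | None = None,
    seed: int = 0,
    **config_overrides,
) -> SimulatedStudy:
    """Build a full linked study: planted crosstalk pairs plus decoy pairs.

    True pairs of each network get concordant DE in the right cell types plus
    a planted bulk correlation of ``rho``.  Half of the decoys have DE genes
    but independent bulk expression (they must be rejected by the
    co-expression filter); the other half are pairs of non-DE genes (rejected
    at the mapping step).
    """
    networks = [
        ("AU", "autocrine_up", n_autocrine_up, [("B", lfc), ("B", lfc)]),
        ("AD", "autocrine_down", n_autocrine_down, [("B", -lfc), ("B", -lfc)]),
        ("BM", "b_to_myeloid", n_b_to_myeloid, [("B", lfc), ("MYELOID", lfc)]),
        ("MB", "myeloid_to_b", n_myeloid_to_b, [("MYELOID", lfc), ("B", lfc)]),
    ]
    de_plan, corr_plan, pairs, true_pairs = [], [], [], set()
    for tag, network, count, ((lig_ct, lig_lfc), (rec_ct, rec_lfc)) in [
        (t, nw, c, (plan[0], plan[1])) for t, nw, c, plan in networks
    ]:
        for j in range(count):
            lig, rec = f"LG{tag}{j + 1:02d}", f"RC{tag}{j + 1:02d}"
            de_plan += [(lig, lig_ct, lig_lfc), (rec, rec_ct, rec_lfc)]
            corr_plan.append((lig, rec, rho))
            pairs.append((lig, rec))
            true_pairs.add((lig, rec, network))
    n_de_decoys = n_decoys // 2
    for j in range(n_de_decoys):  # DE in the B->myeloid direction, no bulk correlation
        lig, rec = f"LGDX{j + 1:02d}", f"RCDX{j + 1:02d}"
        de_plan += [(lig, "B", lfc), (rec, "MYELOID", lfc)]
        pairs.append((lig, rec))
    for j in range(n_decoys - n_de_decoys):  # not differentially expressed at all
        pairs.append((f"LGNULL{j + 1:02d}", f"RCNULL{j + 1:02d}"))

    surv_beta = dict(surv_beta or {})
    defaults = dict(de_plan=de_plan, corr_plan=corr_plan, surv_beta=surv_beta, seed=seed,
                    planted_base_mean_range=planted_base_mean_range)
    defaults.update(config_overrides)
    config = SimConfig(**defaults)
    # decoy null genes must exist in the simulated gene universe
    extra = [g for p in pairs for g in p]
    names = default_gene_names(config.n_genes, config.n_mito_genes, list(dict.fromkeys(extra + list(surv_beta))))
    config.gene_names = names

    counts, annotation, truth = generate_sc(config)
    truth.true_pairs = true_pairs
    bulk = generate_bulk(config, truth)
    records = generate_survival(config, bulk) if surv_beta else []
    db = LigandReceptorDB.from_pairs(pairs, source="synthetic")
    return SimulatedStudy(config, counts, annotation, bulk, records, truth, db)


def write_study(study: SimulatedStudy, outdir, sc_format: str = "mtx") -> dict[str, str]:
    """Persist a simulated study; returns the mapping of artifact -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sc_counts": str(outdir / ("sc_counts.mtx" if sc_format == "mtx" else "sc_counts.tsv")),
        "cell_annotation": str(outdir / "cell_annotation.csv"),
        "bulk": str(outdir / "bulk.tsv"),
        "clinical": str(outdir / "clinical.csv"),
        "lr_db": str(outdir / "lr_pairs.csv"),
        "truth": str(outdir / "truth.json"),
    }
    write_expression(study.counts, paths["sc_counts"], format=sc_format)
    write_cell_annotation(study.annotation, paths["cell_annotation"])
    write_expression(study.bulk, paths["bulk"], format="tsv")
    write_clinical(study.records, paths["clinical"])
    study.lr_db.frame.to_csv(paths["lr_db"], index=False)
    study.truth.write(paths["truth"])
    return paths
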