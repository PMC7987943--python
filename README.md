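# lrcrosstalk

Ligand–receptor crosstalk inference and a prognostic **LR score** for B-cell
precursor acute lymphoblastic leukemia (BCP-ALL) transcriptomics.

In the BCP-ALL bone marrow, malignant B cells and the surrounding myeloid
compartment communicate through secreted and membrane ligands binding their
cognate receptors.  `lrcrosstalk` is for computational biologists who want
to (a) infer which directed ligand→receptor (L-R) edges are
tumor-associated, and (b) turn the genes of those edges into a survival
model.  It implements:

1. **Crosstalk inference.**  Per cell type, every gene is tested tumor vs.
   normal with a two-part *hurdle* test (a detection LRT on the zero
   pattern plus a Gaussian LRT on detected values; the chi-squares add).
   Significant ligands and receptors (BH-adjusted p < 0.05) are intersected
   with an L-R pair database — autocrine B→B edges require concordant
   regulation, paracrine B→myeloid and myeloid→B edges require both genes
   up — and each candidate edge must be co-expressed in an independent bulk
   cohort (Spearman ρ > 0.3, BH-adjusted p < 0.05).

2. **Prognostic LR score.**  On bulk expression of the network genes with
   overall survival, an L1-penalized Cox model
   (min −ℓ(β) + λ‖β‖₁, Breslow partial likelihood, cyclic coordinate
   descent) is refit on 1,000 random 90% patient subsamples with
   per-replicate cross-validated λ.  Genes with nonzero coefficients in
   ≥ 950/1,000 replicates form the final model; their coefficients are the
   replicate averages.  The score of a patient is
   LR = Σ<sub>g</sub> β̄<sub>g</sub> · expr<sub>g</sub>.
   Patients are dichotomized at the score cutpoint maximizing the log-rank
   χ², retained only if significant after correcting for maximal selection
   (Lausen–Schumacher), and evaluated with Kaplan–Meier curves, log-rank
   tests and (multivariable) Cox hazard ratios.

A linked synthetic-data generator (negative-binomial single-cell counts,
Gaussian-copula bulk co-expression, exponential proportional-hazards
survival) provides ground-truth worlds for every stage.  The package also
ships the published 11-gene LR-score model
(`lrcrosstalk.published_model()`).

## Worked example

```python
from lrcrosstalk.pipeline import RunConfig, run_all

config = RunConfig(
    outdir="demo_run", seed=3, n_reps=15, retention_threshold=12, cv_folds=3,
    simulate_params=dict(
        n_genes=1500,
        cell_types={"B": 60, "MYELOID": 40, "T": 30},
        n_tumor_samples=3, n_normal_samples=2, n_bulk_samples=400,
        surv_beta={"RCBM01": 1.2, "RCBM02": -1.1, "LGAU01": 1.2},
    ),
)
report = run_all(config)
print(report["qc"])
print({k: v["n_pairs"] for k, v in report["crosstalk"].items()})
print(report["model"]["final_genes"], report["model"]["avg_coefficients"])
print(report["evaluate"]["train_split"])
```

On this seed the run prints:

```
{'n_input_cells': 650, 'n_kept_cells': 640, 'removed_by_reason': {'low_genes': 10}}
{'autocrine': 7, 'b_to_myeloid': 1, 'myeloid_to_b': 1}
['LGAU01', 'RCBM01'] {'LGAU01': 1.4814544651502923, 'RCBM01': 0.5150069990641222}
{'significant': True, 'cutpoint': 2.2220502461447844, 'chi2': 275.8142582947045,
 'p': 6.134313029035261e-62, 'p_adjusted': 3.729720633409826e-59,
 'n_low': 252, 'n_high': 28}
```

Reading: QC removed 10 borderline low-complexity cells; all 7 planted
autocrine edges are recovered plus one edge in each paracrine direction,
with no false edges.  The 15-replicate ensemble (full-scale default is
1,000 replicates with a 950 retention threshold) retains two of the three
planted hazard genes — `LGAU01` and `RCBM01`, both with correct positive
sign; coefficients are on the raw expression scale.  The survival-tree
cutpoint separates a 28-patient high-score training group with log-rank
p ≈ 6 × 10⁻⁶² (p ≈ 4 × 10⁻⁵⁹ after correcting for cutpoint selection), and
the transferred cutpoint splits the held-out validation cohort at log-rank
p ≈ 4 × 10⁻²².  Recovery at full scale is exercised in
`tests/test_acceptance.py`.

The same pipeline is scriptable via the `lrcrosstalk` CLI
(`simulate`, `qc`, `de`, `crosstalk`, `lrscore fit/apply`, `evaluate`,
`run-all`); all artifacts are plain CSV/TSV/MatrixMarket/JSON.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates a linked study from
the given seed, runs QC, differential expression, crosstalk network
assembly, a 100-replicate stability ensemble and the survival evaluation,
and writes the result JSON to `--out`.
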