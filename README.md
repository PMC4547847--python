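# qdsp-profiler

Statistics for quantitative detergent solubility profiling (QDSP) and
time-resolved tissue proteomics, built for label-free MS studies of tissue
injury and repair (e.g. the bleomycin lung-injury mouse model).

QDSP extracts tissue sequentially with detergents of increasing stringency
into four fractions (FR1, FR2, FR3, INSOL). A protein's intensity profile
across the fractions encodes its solubility — cytosolic proteins elute first,
extracellular-matrix (ECM) constituents stay in the insoluble pellet — so
comparing profiles between conditions separates *where a protein lives* from
*how much of it there is*. Around this idea the package implements the full
analysis stack for three experimental designs:

* **QDSP differential analysis** — per-protein total abundance
  (sum of the four fractions) compared by a two-sided Student *t*-test, and
  solubility change tested as the treatment × fraction interaction of a
  two-way ANOVA on per-condition mean-centered log₂ profiles:

  F_int = [ (RSS_additive − RSS_cellmeans) / (a−1)(b−1) ] / [ RSS_cellmeans / (N − ab) ]

  plus insoluble-intensity shares, abundance ranks, sample PCA and
  correlation-distance hierarchical clustering.
* **Ratiometric time course** — log₂ ratios of each treated replicate over
  the pooled control median, with left-censored (missing-not-at-random)
  values imputed from a downshifted normal N(μ − 1.8σ, (0.3σ)²) of the
  intensity distribution, one-way ANOVA across time points, and per-protein
  ordinary least squares against each mouse's lung-compliance ratio
  (fibrosis stiffens the lung, so fibrosis-associated proteins correlate
  negatively with compliance).
* **BALF / compartment analysis** — a SAM-style enrichment score
  d = (x̄_BALF − x̄_tissue) / (s + s₀), with s the gene-specific scatter
  (pooled standard error) and s₀ an exchangeability constant, separating
  genuine epithelial-lining-fluid proteins from tissue leakage; at s₀ = 0
  the score is exactly the pooled two-sample *t* statistic.
* **Annotation enrichment** — Benjamini–Hochberg FDR, Fisher's exact test,
  and 1D/2D rank-based enrichment where the score is the rank-biserial
  correlation 2U/(n₁n₂) − 1 of the Mann–Whitney U, bounded in [−1, 1].

Every design has a synthetic-data generator with known ground truth
(`generate_qdsp_dataset`, `generate_timecourse_dataset`,
`generate_balf_dataset`), so the whole stack is testable end to end without
any external data.

## Worked example

```python
from qdsp_profiler import GeneratorConfig, generate_qdsp_dataset, run_qdsp

table, truth = generate_qdsp_dataset(GeneratorConfig(n_proteins=2000, seed=7))
res = run_qdsp(table)
stats = res["stats"]
hits = stats[stats["interaction_q"] < 0.05]
print(f"{table.n_proteins} proteins x {table.n_samples} samples")
print(f"{len(hits)} proteins with a solubility shift at FDR < 5%")
cols = ["interaction_F", "interaction_q", "delta_insoluble_share", "total_log2fc"]
print(hits.sort_values("interaction_q")[cols].head(5).round(4))
```

prints

```
2000 proteins x 32 samples
185 proteins with a solubility shift at FDR < 5%
            interaction_F  interaction_q  delta_insoluble_share  total_log2fc
protein_id
P00260           152.3569            0.0                -0.2416        0.0327
P00471           107.3115            0.0                -0.1823        1.8343
P00876           104.3510            0.0                 0.3295        0.2764
P00747           114.2379            0.0                -0.1070        0.2811
P01292            99.6774            0.0                 0.2745       -0.3458
```

32 samples are 2 conditions × 4 replicates × 4 fractions. Each hit's
interaction q-value says its fraction profile differs between conditions
beyond abundance; `delta_insoluble_share` gives the direction (positive =
moved toward the insoluble pellet, i.e. into the ECM), independently of
`total_log2fc`: P00260 relocates without changing abundance, P00471 does
both.

The same analyses run from the shell:

```bash
qdsp-profiler simulate --design qdsp --n-proteins 2000 --seed 7 --output-dir sim
qdsp-profiler qdsp --input sim/proteingroups.tsv --samples sim/samples.tsv \
    --gmt sim/annotations.gmt --output-dir results
qdsp-profiler timecourse --seed 7 --output-dir results_tc   # simulate + analyze
```

Real data enter through `read_protein_groups(path, sample_sheet)`, which
parses the tab-separated proteinGroups dialect of common MS quantification
software (reverse and contaminant rows removed, zero intensities treated as
missing) together with a sample sheet mapping intensity columns to
condition / time point / fraction / replicate / compartment / compliance.
Gene sets (matrisome categories, cell-type signatures, keywords) are read
from GMT files.

## Layout

* `qdsp_profiler.io` — data model, proteinGroups/GMT/sample-sheet readers and
  writers, tryptic-peptide counting and iBAQ stoichiometry, proteome–
  transcriptome matching, z-scoring.
* `qdsp_profiler.synthetic` — ground-truth generators for the three designs.
* `qdsp_profiler.qdsp` — solubility-profile statistics.
* `qdsp_profiler.timecourse` — imputation, ratios, ANOVA, compliance OLS.
* `qdsp_profiler.balf` — SAM compartment score, day-14 test, BALF ANOVA.
* `qdsp_profiler.enrichment` — BH FDR, Fisher, 1D/2D rank enrichment.
* `qdsp_profiler.pipeline` / `qdsp_profiler.cli` — orchestration and CLI.

See `docs/methods.md` for the statistical models, the generator's
assumptions, and the design decisions.
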