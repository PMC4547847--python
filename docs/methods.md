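# Methods

This note documents the statistical models implemented in `qdsp_profiler`,
what the synthetic-data generators do and do not emulate, the numerical
choices, and the places where the design was genuinely open.

## Data model

An `IntensityTable` is a proteins × samples matrix of linear label-free MS
intensities with NaN as the single missingness sentinel. Zero intensities in
input files are converted to missing on read and never treated as measured
zeros: label-free quantification software writes 0 for non-detection, and a
true zero abundance is not observable by MS. Reverse-database hits and
contaminant entries are removed at read time (counts are logged and echoed in
the run metadata) because every downstream statistic assumes a filtered
protein list.

Annotation matching is by gene symbol with protein-id fallback, since the
gene sets this package is used with (matrisome categories, cell-type
signatures, keyword terms) are gene-symbol based.

### Tryptic peptide counting and iBAQ

iBAQ divides a protein's summed intensity by its number of theoretically
observable tryptic peptides, approximating molar abundance. The counting
convention is: fully cleaved peptides only (no missed cleavages), cleavage
C-terminal of K/R suppressed before P, peptide length 7–30 residues. All
four choices are function arguments, not constants, because conventions vary
across software. Stoichiometry vectors (e.g. relative abundance of laminin
chains within the family) are iBAQ values normalized to sum 1 over the
family, with missing members dropped and the remainder renormalized.

## QDSP statistics

Total abundance per biological replicate is the sum of the four fractions'
linear intensities (missing cells contribute nothing; an all-missing
replicate stays missing). Differential abundance is a two-sided Student
*t*-test on log₂ totals — pooled variance by default, Welch by option —
with Benjamini–Hochberg correction across tested proteins.

Solubility change is tested on *normalized* profiles: per protein and
condition, the mean of all non-missing log₂ cells (fractions × replicates
jointly) is subtracted, so both conditions are centered at zero and any
abundance difference cancels. The Methods-level ambiguity of whether to
center per replicate instead is exposed as `per_replicate_centering`. On the
centered values a two-way fixed-effects ANOVA with factors treatment and
fraction is computed; the interaction term carries the signal ("does the
profile *shape* differ between conditions?"). Sums of squares are Type II:

    SS_interaction = RSS(additive model) − RSS(cell-means model),
    F = (SS_int / (a−1)(b−1)) / (RSS_cellmeans / (N − ab)),

which reduces to the classical balanced decomposition when no cells are
missing and remains well defined under unbalanced missingness. A protein
with an empty treatment × fraction cell is reported untested rather than
imputed — imputing inside the interaction test would manufacture the very
signal being tested. Zero residual variance is resolved by convention:
p = 0 (degenerate) if the interaction SS is positive, else p = 1.

The insoluble share is Σ INSOL linear intensity / Σ all-fraction intensity,
pooled over replicates, with missing cells contributing zero mass — linear
sums of detected signal are what an intensity-percentage describes, whereas
log-scale means would weight replicates unequally. The share difference
(BLEO − PBS) gives each detected shift a direction.

PCA is a singular-value decomposition of the column-centered samples ×
proteins matrix (z-scored upstream); the sign convention makes each loading
vector's largest-magnitude element positive, so results are reproducible
across BLAS implementations. Hierarchical clustering uses correlation
distance d = 1 − Pearson r with average linkage by default; constant rows
are a hard error because their correlation is undefined.

Profile-level testing includes proteins with at least
`min_valid_fraction_samples` (default 3) of 4 replicates carrying ≥ 1
fraction value per condition; the inclusion threshold for profile analyses
is a free parameter in this kind of study, so it lives in config.

## Ratiometric time course

Ratios are log₂(treated replicate / pooled control). The control pool is
the median of all valid PBS intensities on the **linear** scale (the
conventional control median; for even counts the linear-scale median is not
the exponential of the log-scale median). For BALF the pool is the mean of
all PBS replicates across time points, taken as the mean of log₂ values
(geometric mean): an arithmetic mean on the linear scale would introduce a
Jensen bias of ½σ²ln2 ≈ 0.04 log₂ units at 25% CV and shift null ratios off
zero.

Missingness in label-free data is left-censored (weak signals fall below
the detection limit), so missing values are imputed from a normal
distribution downshifted into the left tail of the observed intensity
distribution: N(μ − 1.8σ, (0.3σ)²), with μ, σ the mean and sd of the
reference distribution of all per-group log₂ medians (GLOBAL default;
per-column imputation available as PER_SAMPLE). Imputation is gated by
validity rules so that an imputed ratio always contrasts a real measurement
with the detection floor:

* treated replicate valid → MEASURED ratio;
* treated group entirely missing and control ≥ 50% valid → each treated
  cell imputed (IMPUTED_NUM);
* control entirely missing and the treated group ≥ 50% valid → the control
  value imputed once per protein (IMPUTED_DEN);
* anything else → MISSING_RULE, left missing.

Cell-wise (rather than one-draw-per-group) numerator imputation is used
because a single shared draw would give that time point zero within-group
variance and corrupt the downstream ANOVA. Draws come from one seeded
generator in fixed row-major order (protein, time point, replicate;
denominators before numerators), so results are bit-reproducible.

Time-dependence is a one-way fixed-effects ANOVA of log₂ ratios across
time-point groups (a protein needs ≥ 2 time points with ≥ 2 valid ratios).
The compliance analysis regresses each protein's ratios on the per-mouse
compliance ratio (compliance ÷ median control compliance — the denominator
convention is ours, as "compliance ratio" is underdefined in the field) by
ordinary least squares, reporting slope, intercept, Pearson r and the
two-sided t-based p on n − 2 df. Proteins that rise as the lung stiffens
have negative slopes.

## BALF compartment score

The enrichment of a protein in lavage fluid over tissue is scored as

    d = (x̄_BALF − x̄_tissue) / (s + s₀),

with s the gene-specific scatter — the pooled standard error
√[(1/n₁ + 1/n₂)/(n₁+n₂−2) · (Σdev₁² + Σdev₂²)] — and s₀ a small constant
that damps inflated scores at near-zero variance. At s₀ = 0, d is exactly
the pooled-variance two-sample t statistic and p-values come from the t
reference; for s₀ > 0 that reference is invalid, so significance comes from
a label-permutation null (all distinct assignments when ≤ 10,000, else
10,000 sampled with a fixed seed; permutations are vectorized per
missingness pattern). s₀ defaults to the 5th percentile of the s
distribution; a coefficient-of-variation–minimizing percentile search (the
classic automatic tuning) is available as `s0_rule="CV_MIN"`. Comparisons
are made on log₂ intensities, pooling the control samples of each
compartment across time points (mirroring the ratio-denominator pooling;
per-time-point scoring is a config switch). A protein is called
ELF-enriched when d > 0 and its BH q-value clears the chosen FDR.

## Annotation enrichment

The 1D enrichment score of a term is the rank-biserial correlation of the
Mann–Whitney U statistic of members vs non-members, computed as
(2U − n₁n₂)/(n₁n₂) so that score(term) = −score(complement) holds *exactly*
in floating point. Mid-ranks break ties. P-values use exact enumeration for
small tie-free terms (n₁n₂ ≤ 10,000) and the tie-corrected normal
approximation otherwise. The 2D variant scores a term on two data
dimensions and assigns joint significance by permuting membership labels
(statistic max(|score_x|, |score_y|), 10,000 permutations, fixed seed,
add-one p-estimate) — a deliberately assumption-free choice over an
analytic 2D rank test. Fisher's exact test (two-sided, sum of
as-or-less-likely tables) handles categorical foreground/background
enrichment; terms require ≥ 5 scored members by default. Cell-type
signature scoring applies the 1D score per time point to the per-protein
median ratio, flagging |score| significant at α = 0.05.

BH q-values implement the step-up rule q_(i) = min_{j≥i} p_(j)·n/j, capped
at 1, with NaN p-values passed through untested.

## Synthetic data

The generators emulate the three study designs with the field's canonical
dimensions: QDSP as 4 fractions × {PBS, bleomycin} × 4 replicates; the
tissue time course as treated day 3 n=3, day 14 n=7, day 28 n=4, day 56
n=3 against 16 pooled controls; BALF as paired lavage + tissue compartments
with 4 mice per condition at 6 time points (n = 48 per compartment).

Per protein: a compartment class (cytosolic 35%, membrane 25%, nuclear 15%,
cytoskeletal 15%, ECM 10%) sets a fraction-mass template (e.g. cytosolic
(0.70, 0.20, 0.07, 0.03), ECM (0.02, 0.05, 0.13, 0.80) — ECM mass sits in
the insoluble pellet). Total abundance is log-normal (log₂ mean 25, sd 2.5,
arbitrary MS units). Replicate noise is multiplicative log-normal at 25%
CV — a typical biological-replicate CV for label-free tissue proteomics.
Detection follows a logistic curve in log₂ intensity (midpoint 16, slope 1),
so missingness is left-censored and monotone in expected intensity, matching
the assumption behind the downshifted-normal imputation.

Injury effects: 10% of proteins shift solubility by convex mass transfer
between the FR1 and INSOL template ends (mass 0.25), which keeps the
direction label well defined; the direction runs *away* from a protein's
resting end (soluble proteins coagulate into the matrix, insoluble
basement-membrane constituents solubilize), as a shift further into an
already-dominant end would be a near-no-op with an ill-defined label. 30%
of proteins change abundance with amplitudes N(0, 1.5²) log₂ units spread
over three temporal archetypes (early-peak, fibrotic-peak,
late-resolution) — a regime in which roughly half the quantified proteome
responds, as is characteristic of severe transient tissue injury.
Fibrotic-archetype amplitudes are positive (fibrosis proteins accumulate),
and their per-mouse effect scales with a latent fibrosis burden that peaks
at day 14; compliance = baseline · exp(−coupling · burden + noise) with
log-normal noise (compliance is a positive physiological quantity), so
burden induces negative protein–compliance correlations of known sign. In
BALF, expected intensity is elf_weight · secretion + leakage_weight ·
tissue level with elf_weight ≫ leakage_weight (1 vs 0.02) for the 15% of
proteins flagged as epithelial-lining-fluid members; secretion sits
N(2, 1) log₂ units above the tissue level.

What the generators do **not** emulate: peptide-level evidence, intensity-
dependent CVs, inter-sample normalization artifacts, correlated protein
modules, batch effects, plasma-contamination gradients, or tissue remodeling
of the BALF leakage term over time. Passing recovery tests therefore shows
that the statistics recover the effects they model under realistic noise and
censoring — not that they are robust to every artifact of real MS data.

## Numerical choices and degenerate inputs

* Tests return NaN (untested) when their preconditions fail (< 2 values per
  group, empty design cells, zero regressor variance) and the run log counts
  them; degenerate zero-residual cases resolve to p ∈ {0, 1} by the sign of
  the effect sum of squares.
* BH, rank scores, and permutation p-values are computed with exact integer/
  half-integer arithmetic where it matters (antisymmetry, step-up order).
* All randomness flows from seeded `numpy` generators; dataset seeds are
  namespaced per design so the three generators are independent at the same
  seed. Result tables are written with fixed formatting, making identical
  config + seed runs byte-identical.
* Imputation requires a reference distribution of ≥ 30 values with positive
  spread; it is validated lazily, only when draws are actually needed.

## Problem sizes

The bundled analyses and checks run at 2,000–5,000 proteins — the scale at
which the recovery rates and error levels stabilize (binomial se ≲ 0.005 at
n = 5,000) while a full run of every design completes in well under a minute
on one CPU. All sizes are plain config fields.

## Known limitations

* Imputation-based ratios can flag proteins hovering at the detection limit
  as "regulated" (groups alternating between measured and floor-imputed
  values); the BALF time-course ANOVA is most exposed. The provenance matrix
  makes such calls auditable, and stricter valid-value filters are available
  upstream; a minimum-measured-fraction filter inside the ANOVA is a
  deliberate non-feature, to keep the test faithful to its definition.
* The two-way ANOVA treats replicates as independent; mouse-level pairing
  across fractions is not modeled (no mixed effects, by scope).
* The 2D enrichment p-value is permutation-based and hence granular at
  1/(n_permutations + 1); at 10,000 permutations the smallest attainable
  q-values are bounded accordingly.
* `CV_MIN` s₀ selection uses a decile-binned coefficient-of-variation
  criterion; with very few tested proteins (< ~100) the bins are unstable
  and the percentile rule is preferable.
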