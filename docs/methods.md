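# Methods

This note records the models, conventions and numerical choices behind
`imputeval`, in the order the pipeline applies them.

## Synthetic cohort model

The generator emulates a multi-centre preclinical serum-chemistry study:
`n_studies` (default 107) single-toxin studies of 30 animals each, animals
1–10 controls, 11–20 low dose, 21–30 high dose, two samples per animal (24 h
plus 48 h or 168 h, alternating deterministically by animal parity). Studies
are allocated to the five companies round-robin by default; an explicit
`studies_per_company` map reproduces unbalanced consortia.

**Marginals.** Analytes are log-normal (positive, right-skewed — the shape
clinical-chemistry panels typically show), with per-analyte log-scale
location/scale defaults loosely matching rat serum reference ranges. Only
positivity is essential; none of the downstream machinery depends on the
exact shape.

**Dependence.** Non-pair analytes share a mild exchangeable latent
correlation (ρ = 0.2) through a Gaussian copula, so imputation engines have
some signal to exploit everywhere. Each planted pair is generated as
`response = slope·predictor + intercept + ε` with `ε` Gaussian. Writing `c`
for the batch-shift scale (below), independent additive shifts on both pair
members bound the observable squared correlation by `1/(1+c²)²`; the noise
variance is solved in closed form so the *observed* R² (shifts included)
hits the target:
`σ² = a²·Var(x)·(1/((1+c²)²·R²) − 1)`.
Targets above the bound raise `spec-infeasible`. With the defaults
(c = 0.2) the planted R² of 0.86 and 0.72 are reproduced within ±0.05 at
cohort sizes ≥ 3000 rows.

**Batch effects.** One additive offset per (study, analyte), drawn
`N(0, (c·SD_analyte)²)` and applied identically to every sample of the
study — the structure a shift-based (median-centring) correction removes
exactly. Default c = 0.2 keeps the planted correlations feasible while
making between-study differences obvious in control medians.

**Dose effects.** High/low-dose rows get a multiplicative bump (×1.4 / ×1.15)
on a configurable analyte subset, by default analytes *outside* the planted
pairs so the R² targets are not diluted. This keeps non-control structure in
the data without entangling the bias metric.

**What the generator does not emulate:** real units and reference ranges,
time trends within animals, heteroscedastic assay noise, correlated
missingness already present at collection, and label noise in metadata.
Passing benchmarks on this cohort therefore demonstrate correctness of the
machinery and the qualitative strategy ordering under known structure — not
performance guarantees on any particular real dataset.

## Curation and median centring

Fixed order: explicit exclusions → negative values masked → sparsity filters
(columns > 40% missing dropped, the boundary retained; all-missing rows
dropped) → fit and apply median centring → re-mask cells the shift turned
negative → complete cases. The 40% default is configurable.

The correction is fitted on controls only and applied to all rows. `GM` is
the pooled median of 24-h control samples across studies; `SM` the per-study
median of controls at all timepoints (a config switch makes GM use all
timepoints too). Shift mode computes `x' = x − (SM − GM)`; ratio mode
`x' = x·GM/SM` (cells with `SM = 0` are left uncorrected and logged). Medians
use midpoint interpolation on even counts. Because the median is
shift-equivariant, each study's control median lands exactly on `GM` after
shift correction (up to float rounding), except where post-correction
negativity masking removed a control cell. Negative corrected values are
masked, not clamped: the correction is allowed to create sparsity rather
than fabricate zeros.

## Amputation

The mask has exactly `round(M·n·p)` cells, split across columns as evenly as
possible (remainder to a seeded random subset), so no column is accidentally
emptied. Within a column: MCAR draws rows uniformly; MAR weights rows by the
rank of a driver column (cyclic assignment `j → j+1 mod p` unless mapped);
MNAR weights rows by the column's own ranks. Weights are `rank/Σrank` and
sampling is without replacement, so repeated seeds vary rather than always
deleting the same top fraction. All probabilities are computed from the
complete pre-amputation matrix — the standard simulation convention, which
also guarantees deletion decisions never depend on values the mask removes.
Metadata (`Y`, `C`) is never masked; the proportion is counted over analyte
cells only.

## Engines

Both engines use bagged CART forests (bootstrap sampling, `mtry =
floor(√p)`, `min_leaf = 5`, `ntree = 10` by default). Only `ntree` is a
studied hyperparameter; the rest are standard defaults and deliberately not
tuned. Categorical features are one-hot encoded for the tree learner. A thin
forest wrapper over scikit-learn's decision trees skips per-fit parameter
validation (the benchmark fits ~10⁵ very small forests; validation would
dominate runtime) and is exercised by the same contract tests as the
engines.

**Iterative engine (missForest algorithm).** Initialise missing cells with
column means (modes for categoricals); visit target columns in order of
increasing missingness; for each, fit a forest on the rows where the column
is observed (all other columns as features) and predict its missing cells.
After each sweep compute `Δ = Σ(new−old)²/Σnew²` over the imputed continuous
cells (and the disagreement fraction for categorical targets). Stop when Δ
rises or after `max_iter` (default 10) sweeps, returning the previous
sweep's completion on a rise. An input with no missing cells returns
immediately (`stopped_reason = "no-missing"`). The 53-level factor cap is
enforced for this engine only — it is a limitation of the classical
random-forest implementation this algorithm is built on — so the 107-level
toxin factor cannot be one of its features.

**Chained engine (MICErf).** `mice_m` chains (default 5), each initialised
by random draws from the observed values and swept `mice_iterations` times
(default 5). A missing cell is filled by choosing one tree of the column's
forest uniformly, locating the cell's leaf, and drawing uniformly among the
observed responses in that leaf — so every imputed value is an observed
donor value. An empty leaf (impossible with donors defined over the full
observed set, but guarded anyway) falls back to the deepest non-empty
ancestor node. Chains are merged cell-wise (mean; mode with lexicographic
tie-break for categoricals). No factor cap applies. The chain count is not a
quantity the evaluation studies; the benchmark-scale runs below use
`mice_m = 3` to keep the full grid affordable, while the engine default
remains 5.

## Strategy grid

Eleven cells: feature sets {X, X+C, X+Y+C, X+Y+Toxin+C} crossed with
C-as-variable vs per-centre stratification, minus the iterative-engine ×
toxin cell (factor cap). `Y_All` excludes the toxin label. In strata mode C
is constant within a stratum and is excluded from the features; the
strategy's feature set is otherwise honoured inside each stratum. Stratum sub-seeds
derive from (seed, stratum label), so per-stratum runs are reproducible in
isolation; a single-level C degenerates exactly to the pooled run. A stratum
where any analyte has fewer than two observed values is *infeasible*; the
strategy reports every infeasible (stratum, analyte) pair and the harness
records the failure as a flagged row instead of aborting the grid — the
small-sample failure mode characteristic of stratified chained-equations
runs.

## Metrics

NRMSE uses the population-variance convention (divide by n), which makes
masked-truth-mean imputation score exactly 1 — asserted as a calibration
test. Full MAE pools all masked cells after dividing each analyte's absolute
errors by the analyte's truth SD (analytes have incommensurate units); a
`raw` pooling switch disables the harmonisation. Partial MAE is per-analyte
in raw units; analytes with no masked cells are absent, not zero.
Relationship bias is the absolute slope error of a known linear pair,
reported both for the imputed data and for the complete-case baseline,
against the slope fitted on the full truth (so the metric is usable on real
data where the generating slope is unknown); intercept errors are emitted
alongside. Distribution shift is the two-sample KS statistic between truth
and post-imputation columns.

## Harness

Within a repetition every strategy receives the identical mask (paired
design — it removes between-strategy mask noise from the comparison), and
masks are re-drawn per repetition by default (`fixed_masks` reuses one mask
per condition). Per-cell seeds derive from (master seed, N, mechanism,
proportion, repetition), so any cell reproduces in isolation. Sample-size
reduction subsamples the complete-case pool with a seeded draw. Aggregation
reports mean and sample SD (ddof = 1; a single repetition yields an
undefined SD, not 0) over non-failed repetitions plus a failure fraction.
Ranking is by mean full MAE, ties by mean NRMSE then label; strategies with
failures rank after all clean ones, flagged.

## Problem sizes

Defaults follow the study design: 20 repetitions, sample sizes
{3817, 500, 50}, the 15-condition missingness grid, 11 strategies. The
package's own benchmark-scale configuration — used by the acceptance tests
and `scripts/acceptance.py` — runs N = 500 with 5 (tests) or 2 (script)
repetitions and `mice_m = 3`, which reproduces the qualitative conclusions
in minutes on one CPU. The conclusions asserted at that scale are
directional (majority-of-cells statements and curve monotonicity), not
point estimates.

## Known limitations

* MAR conditions on other analyte columns, not metadata (a driver map can
  point anywhere, including metadata turned into ranks by the caller).
* The chained engine collapses chains to a single completed table; it does
  not implement Rubin's-rules pooled inference, coverage, or confidence
  validity.
* No predictive-downstream evaluation (e.g. refitting toxicity models on
  imputed data).
* Free-text metadata harmonisation and judgment-based "failed experiment"
  detection are out of scope; an explicit exclusion list stands in for the
  latter.
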