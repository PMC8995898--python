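# Methods

This note documents the models, procedures, parameter choices and known
limitations of `cytomodules`. Everything quantitative stated here is
recomputed by the test suite or `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Feature derivation

Per-cell intensities are transformed with `arcsinh(x / cofactor)`,
cofactor 5 (the standard choice for mass-cytometry ion counts; exposed as
`featurizer.cofactor`). Features are medians per (cell type, protein)
within a sample, minus the donor's matched unstimulated median. Choices:

- **min_events = 20** per cell type per sample: medians over fewer events
  are unstable; such entries are missing, and missingness propagates to
  the deltas (never imputed as zero). Downstream correlation uses
  pairwise-complete donors with the pair count recorded; pairs backed by
  fewer than 3 donors are missing.
- **Responsiveness threshold 0.2** on the *signed* cohort mean delta,
  inclusive (`>= 0.2`). The inclusive boundary is a determinism choice.
  Using the signed mean drops strong negative responders; pass
  `use_absolute=True` to keep them. The unstimulated condition is part of
  the feature enumeration (its deltas are identically zero), which is what
  makes the 16 × 9 × 15 = 2,160 identity hold, and the threshold then
  removes it.

## Module detection

Pearson correlation across donors (Spearman available), average-linkage
clustering on `d = 1 − R`. The distance deliberately uses `R`, not `|R|`:
anti-correlated features should not co-cluster, since modules are positive
blocks. Missing correlations enter the distance as 0 (d = 1) and
zero-variance features, whose correlations are undefined, can never join a
module.

Module extraction replaces a manual box-drawing step with a deterministic
rule: the maximal dendrogram clades with ≥ `min_size` (4) leaves whose
positive-edge density in the `|R| > 0.5` ternarized adjacency is ≥
`min_density` (0.5); the top-down search stops at the first qualifying
clade. Both parameters are exposed.

**Known limitation of the clade rule.** Two internally dense but mutually
uncorrelated blocks of sizes (a, b) merge into a clade of density
`(C(a,2)+C(b,2))/C(a+b,2)`, which exceeds 0.5 once the size ratio passes
roughly 2.5 — the rule then reports the union. The simulator's default
programs (9–12 features each) sit below that ratio; with very unbalanced
real modules, raise `min_density` or lower `min_size` judiciously.

Module attribute summaries flag the attribute axis (protein / cell type /
condition) with the lowest normalized entropy of member values as
dominant; exact ties report "none".

## Module scores

"Normalized" is interpreted as the z-score across donors (sample sd),
the standard choice when averaging heterogeneous features; min–max
normalization is available as an option. Scores are means over member
z-features, ignoring missing members; a donor missing every member gets a
missing score. Unassigned features are scored as their own pseudo-module.

## Sex-stratified statistics

Per-sex correlation matrices share the full-cohort clustering order.
The distributional comparisons use hand-implemented primitives:

- **Wilcoxon rank-sum**: midranks, exact enumeration over all
  `C(n1+n2, n1)` splits when both samples have ≤ 10 observations,
  otherwise a normal approximation with tie-corrected variance and
  continuity correction.
- **Two-sample KS**: `D = sup |ECDF_x − ECDF_y|` with the limiting
  Kolmogorov tail at effective size `n·m/(n+m)`. Group sizes here are
  ~40+, where the asymptotic tail is adequate; exact small-sample KS is
  out of scope.
- **Benjamini–Hochberg** step-up across each family: the per-module
  correlation family and the module-score KS family each span all modules
  plus the unassigned pool (12 tests at the default planted count of 8
  modules + unassigned would be 9; the family size follows the detected
  modules).

**Known limitation (deliberately replicated).** The per-module Wilcoxon
treats pairwise correlation coefficients as exchangeable observations.
They are not: all pairs within a module are estimated from the same donors
per sex, so sampling noise in a sex's donor draw shifts the module's whole
pair-R distribution coherently, and the test is structurally
anticonservative under the null — on simulated null cohorts it rejects
2–7 module families per cohort at BH-adjusted 0.05. This replicates the
procedure as practiced in this analysis style; treat its per-module flags
as descriptive. `bootstrap_correlation_difference` provides a
donor-bootstrap alternative whose null behavior is calibrated, and the
module-score KS family (a valid independent-sample test) shows no such
inflation (zero null rejections across 20 simulated cohorts).

## SAM differential features

`d = (x̄₁ − x̄₂)/(s + s₀)` with the pooled standard error `s` (pairwise
deletion for missing values) and `s₀` chosen from the 0,5,…,100 percentile
grid of `s` to minimize the coefficient of variation of the windowed
median |d| (windows are quantile slices of `s`; the window count caps at
`n_features/5` below 500 features so windows stay populated). Label
permutations (default 1000; exhaustive when `C(n, n1)` ≤ 10,000) give null
statistics; at each |d| threshold the FDR is a percentile of the null
exceedance count over permutations divided by the observed count (π₀ = 1,
conservative), and q-values are suffix-minima, hence monotone in |d|.

**Null-count percentile = 90 by default.** With block-correlated features
— precisely what signaling modules create — null exceedance counts are
zero-inflated and bursty: most permutations exceed a high threshold zero
times, a few exceed it module-at-a-time. The median then understates the
false-positive load and produces spurious q < 0.01 calls on null cohorts
(8 of 20 simulated null cohorts call ≥ 1 feature); the 90th percentile,
the robust summary offered alongside the median in the original SAM
procedure, restores calibration (19 of 20 cohorts call none) while the
planted-shift power and protein grouping are unchanged. Set
`null_percentile=50` for the median variant.

## Penalized classifiers

One monotone proximal-gradient solver covers ridge, lasso, elastic net,
group lasso and sparse group lasso on the mean logistic deviance; the
intercept is unpenalized; group weights are `√p_g`. Numerical choices:

- Backtracking line search (halving) with a gentle step-size recovery;
  a Nesterov acceleration step is taken only when it does not increase
  the objective, so the objective path is non-increasing by construction.
- Convergence when the objective decrease falls below
  `tol·(1 + |objective|)`; hitting `max_iter` flags the fit rather than
  failing silently. At the smallest λ values on separable data no finite
  minimizer exists and such flags are expected.
- The KKT diagnostic is the fixed-point residual of the unit-step
  prox-gradient map; unpenalized fits agree with a Newton solver to
  `‖Δβ‖∞ < 1e-4` and lasso coincides with singleton-group sparse group
  lasso at α = 1 to `1e-6` (asserted in tests).
- λ grids run log-spaced from λ_max (smallest λ with all-zero solution;
  for the mixed sparse-group penalty found by bisection on the block
  subgradient condition) down 4 decades. Ridge has no sparsity threshold,
  so its grid anchors at 100× the gradient scale.
- Cross-validation: stratified k-fold (default k = 10, 3 repeats),
  held-out mean deviance, ties toward the larger λ, warm starts down each
  λ path. Multi-seed experiments and the replication script use the
  scaled settings k = 5, 1 repeat, 8 λ points, which select comparably
  on these problem sizes.
- Standardization is computed on training donors and applied to test
  donors; module-score models likewise normalize features on training
  donors only. Unassigned features enter group penalties as singleton
  groups (configurable to one shared group). Classification threshold
  p = 0.5.

## The synthetic cohort generator

The generator emulates the *statistical* structure of a stimulation
cohort, not raw cytometry: events carry pre-assigned cell-type labels
(gating is out of scope), and spillover, beads, doublets and barcoding
artifacts are not simulated. Construction, per donor d and sample
(condition s):

```
target(p, c) = base(p, c) + ζ(d, s, p, c)
             + 1[responsive] · (effect + shift_sex(p) + loading_sex(p)·z(d, p))
cell value   = target + N(0, cell_noise_sd);   raw = 5·sinh(value)
```

with `z(d, p)` standard-normal donor latents. Raw intensities invert the
featurizer's transform exactly. Defaults and why:

| parameter | default | role |
|---|---|---|
| n_donors | 86 | cohort size under study |
| conditions / cell types / proteins | 16 / 9 / 15 | panel dimensions (2,160 features) |
| cells_per_sample | 1000 | median sampling error ≈ 0.01, negligible vs biology |
| effects | 0.8–1.3 | responsive features clear the 0.2 threshold with margin |
| loading (per sex) | 1.0 | latent scale; within-program pair R ≈ 0.70 |
| sample_noise_sd | 0.46 | idiosyncratic per-sample variation; sets the 0.70 |
| cell_noise_sd | 0.25 | cell-to-cell spread on the arcsinh scale |
| cell-type proportions | blood-like, Dirichlet conc. 1000 | rare populations (~3%) occasionally dip under min_events, exercising the missing-data path |

The cell-level distribution is Normal on the transformed scale (so the
median equals the targeted mean — medians are the only statistic consumed
downstream), and the unstimulated sample's ζ is shared by all of a
donor's deltas for the same (protein, cell type), giving the mild extra
correlation across conditions that real baseline variation would.

Eight protein programs (9–12 features each, 82 features total) are planted
by default. Named study conditions:

- `sex_coordination_config()`: female loading 1.4 vs male 0.6 in six of
  the eight programs (pSTAT1, pSTAT5, pSTAT6, pERK1/2, pP38, pCREB) —
  planted within-program pair R ≈ 0.82 (F) vs 0.46 (M), means untouched.
- `sex_shift_config()`: +0.8 (arcsinh scale) male-higher on pSTAT1 and
  pTBK1 responses, +0.8 female-higher on pERK1/2, pP38 and pCREB — a
  per-feature standardized effect of ≈ 0.67, chosen by power analysis to
  give per-feature t ≈ 3 at n = 86 and a combined five-program
  discriminant large enough for held-out AUC well above 0.75.

**What passing tests do and do not show.** Recovery and calibration on
these cohorts demonstrate that the pipeline finds the structure it is
designed for and stays quiet in its absence, at realistic noise. They do
not certify behavior under features of real data the generator omits:
gating errors, batch effects, heavy-tailed or skewed event distributions,
unbalanced or confounded demographics, and module structure that is not
protein-aligned.

## Problem sizes used in checks

Multi-seed experiments use 20 simulated cohorts for recovery and null
calibration, 3–5 cohorts for planted-effect recovery (held-out AUC is
reported as the median across cohorts since a 36-donor test set carries
an SE of ≈ 0.08), and the replication script uses 10/10/2/3 cohorts for
the same four experiment families.
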