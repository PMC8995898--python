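# cytomodules

Analysis of stimulation-response mass-cytometry profiling: from gated
single-cell event tables to donor-level immune features, correlated-feature
modules, sex-stratified coordination statistics, permutation-based
differential features (SAM), and module-structured penalized classifiers.

The package is aimed at immunologists and computational biologists working
with phospho-protein stimulation panels (CyTOF or flow): cohorts of donors
whose blood is split into aliquots, stimulated *ex vivo* with a panel of
cytokines, growth factors and microbial agonists, and measured per cell for
intracellular signaling readouts (pSTAT1, pERK1/2, pP38, ...) within gated
immune populations.

## The model

**Immune features.** For each donor, condition *s*, cell type *c* and
signaling protein *p*, intensities are variance-stabilized with
`t = arcsinh(x / 5)` and summarized by the per-population median
`m(p, c, s)`. The immune feature is the stimulation delta

```
Δ(p, c, s) = m(p, c, s) − m(p, c, unstim)
```

At 16 conditions × 9 cell types × 15 proteins this enumerates 2,160
features per donor; features whose cohort mean Δ falls below 0.2 are
treated as non-responsive and dropped.

**Modules.** Features are Pearson-correlated across donors, hierarchically
clustered on `d = 1 − R` (average linkage), and the map is ternarized at
`|R| > 0.5` into an adjacency matrix. Modules are the maximal dendrogram
clades of ≥ 4 features whose positive-edge density is ≥ 0.5 — an automated
stand-in for drawing boxes around the visually contiguous high-correlation
blocks. Each donor's **module score** is the mean of the z-normalized
member features.

**Statistics.** Sex-stratified correlation matrices are compared globally
and per module with a hand-implemented Wilcoxon rank-sum test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise); module-score distributions with a two-sample Kolmogorov–Smirnov
test; both families Benjamini–Hochberg adjusted. Differential features use
the SAM moderated statistic `d = (x̄₁ − x̄₂)/(s + s₀)` with a permutation
FDR (q < 0.01).

**Classifiers.** Donor sex is predicted by penalized logistic regression
solved with a monotone proximal-gradient method:
ridge `λ‖β‖₂²/2`, lasso `λ‖β‖₁`, group lasso `λ Σ_g √p_g ‖β_g‖₂` and
sparse group lasso `λ[α‖β‖₁ + (1−α) Σ_g √p_g ‖β_g‖₂]`, with modules as
groups, λ (and elastic-net α) tuned by repeated k-fold cross-validation,
and evaluation on a held-out 50/36 donor split (accuracy at p = 0.5, rank
AUC).

**Synthetic cohorts.** Because the real cohort is an external repository
download, the package ships a first-class simulator: each donor draws one
latent propensity per signaling protein, injected into the target medians
of every responsive (protein, cell type, condition) triple — so responses
of one pathway co-vary across the donor's cell types and stimuli, which is
exactly the module structure the detector is supposed to find. Sex effects
are plantable through two orthogonal knobs: per-protein factor-loading
scales (coordination differences) and per-protein mean shifts (response
differences).

## Worked example

`examples/02_detect_modules.py` simulates the default cohort (86 donors,
16 conditions, 9 cell types, 15 proteins, 1000 cells/sample), derives and
thresholds features, and extracts modules:

```
8 modules among 90 retained features
within-module mean R 0.68 vs overall mean R 0.06 (modules are far more
internally correlated than the background)
        n_features        proteins dominant_attribute
module
1                9          pSTAT6            protein
2                9           pTBK1            protein
3                9           pCREB            protein
...
```

Eight planted signaling programs come back as eight modules, every one
dominated by its signaling protein rather than by cell type or stimulus,
and within-module correlation (0.68) far exceeds the background (0.06).
The other examples cover feature derivation (`01`), sex-stratified
statistics and SAM (`03`), and the classifiers (`04`):

```
model                    accuracy    AUC  selected
ridge                        0.78   0.88        66
lasso                        0.69   0.79        11
group_lasso                  0.72   0.81        66
sparse_group_lasso           0.75   0.83        40
module_score_lasso           0.75   0.84         6
```

A thin CLI mirrors the library for shell use:
`cytomodules simulate|derive|modules|scores|stratify|differential|predict|run`,
each accepting `--config cfg.yaml` and `--seed`.

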