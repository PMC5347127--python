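# Methods

## Model and procedure

`pccorrnet` infers a *discriminative correlation network*: a signed,
weighted graph over omic features in which an edge is strong only when
its two endpoints are simultaneously (i) strongly Pearson-correlated
across samples and (ii) strongly loaded on the principal component that
separates the sample groups. The pipeline is unsupervised up to the
final labelling step: PCA finds the separation, labels are only used to
test it and to orient node colours.

Steps, with the conventions this implementation fixes:

1. **Preprocessing** (`preprocess`). Optional: none (default), per-feature
   z-score (sample sd, n−1), or log1p. The same preprocessed matrix feeds
   PCA, the Pearson matrix, and the univariate screens, so all views of
   the data are consistent. Genotype matrices coded 0/1/2 with missing
   code 3 can be mode-imputed per SNP first (`impute_mode`; ties toward
   the smallest code, for determinism).
2. **PCA** (`fit_pca`). SVD of the column-centred or raw matrix; loadings
   are exact unit-norm right singular vectors. Eigenvector sign is
   arbitrary, so each loading column is flipped to make its
   largest-magnitude entry positive; downstream node colours and LOOCV
   averaging depend on this determinism.
3. **Component selection** (`select_discriminative_pc`). Both centerings ×
   PC 1..2 (configurable) are scored by a two-sided Mann–Whitney U test on
   the PC scores (exact when both groups ≤ 8 and tie-free, normal
   approximation with tie correction otherwise; Kruskal–Wallis for > 2
   groups). The winner is the smallest p-value, ties preferring centred
   PCA and the lower PC. Because up to four correlated hypotheses are
   scanned, the significance call compares the best p-value against
   alpha/m (Bonferroni, m = candidates scanned). Without this correction
   a pure-noise dataset would be declared "discriminative" in roughly
   15–25% of runs, and any network built from it would be an artefact;
   with it the measured false-alarm rate is ~2% (see the null control in
   the acceptance run). When nothing is significant the method declines
   to produce a network.
4. **Loading processing** (`normalize_loadings`, `scale_loadings`).
   `V*(i) = sign(V(i))·log10(1 + |V(i)|/mean|V|)`, then division by
   `max|V*|`. Sign and magnitude rank order are preserved exactly; the
   processed loadings span [−1, 1] like correlations, which is what makes
   the min operator meaningful.
5. **Edge fusion** (`pccorr_edge`): `sign(c_ij)·min(|c_ij|, |v_i|, |v_j|)`.
   The sign always comes from the correlation. Constant features get
   correlation 0 (warning) rather than an error, since real omic tables
   contain constant columns.
6. **Thresholding** (`threshold_network`). Non-strict comparison
   `|w| ≥ cutoff` (deterministic at exact ties), cut-off in (0, 1];
   singletons removed. Node group = the group whose samples have the
   higher median of the feature; colour is a linear gradient from white
   at |v_new| = 0 to red (first group) or black (second group) at 1.
   Node degree is recorded for display sizing.
7. **Frustration** (`compute_frustration`, `resolve_frustration`). An edge
   is frustrated when its sign contradicts the product of its endpoint
   loading signs. Policies: `report` (annotate), `drop` (remove the
   frustrated edges when they are < 5% of all edges, otherwise refuse),
   `raise` (step the cut-off up by 0.01 until the fraction is 0 or the
   network empties). The 0.01 step matches the two-decimal granularity at
   which cut-offs are conventionally quoted.

### Baselines

The **P-value network** screens every feature (two-sided Mann–Whitney,
Benjamini–Hochberg via `statsmodels`, adjusted p ≤ 0.05) and connects
significant features with Pearson edges at the same cut-off. Fewer than
two significant features is a regular outcome, not an error: the network
"does not exist" (`exists=False`). Node value is the group median
difference (first group minus second), rescaled by its maximum for the
colour gradient.

The **P-value MI network** replaces Pearson edges by the context
likelihood of relatedness: Gaussian MI `−½ln(1−r²)` (|r| = 1 capped at
0.999999 with a warning), per-row z-scores clamped at 0 (population sd;
zero-sd rows give z = 0), pair score `sqrt(z_i² + z_j²)`. CLR scores are
min–max rescaled to [0, 1] before thresholding so the same cut-off scale
as the correlation networks applies; this rescaling is a convention of
this implementation and is recorded in the network metadata. Other MI
inference variants (ARACNE, MRNET, MRNETB) are deliberately not
implemented; CLR is the one exercised in practice.

`match_node_count_cutoff` supports cutting a large baseline network at
the level that approximately matches the PC-corr network's node count
(largest swept cut-off with count ≥ target and closest to it, ties to
the higher cut-off).

### LOOCV robustness

PCA is repeated with each sample left out, keeping the component index
and centering fixed from the full data (re-selecting per iteration would
conflate component identity with stability). Each iteration's loading
vector is sign-aligned to the full-data vector (flip when the inner
product is negative; flips are logged) — without alignment, averaging
arbitrarily-signed eigenvectors is meaningless. Per-iteration PC-corr
matrices are built on the reduced (n−1)-sample correlation matrices and
combined entrywise by average, median and minimum absolute value; the
min-abs network is the intersection network, its sign taken from the
full-data matrix with sign-unstable entries flagged. A speed filter
drops features whose maximum |v_new| across iterations is below the
cut-off before computing correlations; the filter uses a non-strict
comparison so that, by the min-operator bound |w| ≤ |v_new|, it provably
cannot change the thresholded networks (verified by an equivalence
test). The robustness score is the fraction of original edges retained
in the min-abs network at the same cut-off. Removals that would leave a
labelled group with fewer than two samples are skipped with a warning.

## Synthetic data

The generator plants equicorrelated Gaussian blocks (pairwise
correlation ρ, sampled via the Cholesky factor of the equicorrelation
matrix) plus i.i.d. noise; a block's group shift is δ standard
deviations applied to the second group. Presets:

* `and_gate` (n = 20/20): one block (12 features, ρ = 0.8, δ = 3), one
  correlated-only block (12, ρ = 0.8, δ = 0), five shifted singletons
  (δ = 0.75, alternating sign), 25 noise features. The singleton shift
  is deliberately modest: a pooled two-group sample *mechanically*
  correlates any two shifted features (r ≈ (δ₁δ₂/4)/…), so a large δ
  would contradict the category "discriminative but uncorrelated". At
  δ = 0.75 the true pooled correlation of a singleton with the main
  block stays well below the 0.5 cut-off.
* `metagenomics_like` (n = 8/8): one wide panel of 60 weakly shifted,
  weakly correlated features (ρ = 0.05, δ = 0.65) plus 50 noise
  features. The regime is multivariately separable (the PC aggregates
  ~60 near-independent small effects) but univariately hopeless after
  BH. The weak-ρ choice is essential: strongly correlated features have
  co-moving p-values, so BH fires for the whole block at once and the
  univariate/multivariate contrast disappears.
* `lipidomics_like` (n = 20/20): blocks (8, 0.8, +2.5), (6, 0.7, −2.0),
  (6, 0.6, +1.5), (5, 0.5, 0) plus 25 noise features — mixed strengths
  and both shift directions, as in a two-sex lipid panel.
* `null` (n = 20/20): 50 noise features.

What the generator does *not* emulate: count/compositional noise,
heteroscedastic intensities, LD structure, batch effects, or heavy
tails. Passing tests therefore demonstrate the method's selectivity and
stability under clean Gaussian block structure, not robustness to
platform-specific artefacts.

## Numerical choices and degenerate inputs

* Non-strict threshold comparisons (`≥`) everywhere a cut-off is applied.
* All-identical observations give Mann–Whitney p = 1 rather than NaN.
* An all-zero loading vector is an error (the scaling factor mean|V|
  would vanish); a zero entry in `v_new` simply annihilates that row of
  the network.
* Empty networks are legal (warning); their frustration fraction is 0 by
  convention.
* BH adjustment and Mann–Whitney are checked against independent
  hand-rolled oracles (literal step-up; exhaustive permutation
  enumeration for all two-group splits of n ≤ 10).

## Known limitations

* No automatic cut-off optimisation; the cut-off is an exploration
  parameter for the operator.
* Multi-group (> 2) discrimination uses Kruskal–Wallis and attributes a
  node to the group with the highest feature median — an extension
  beyond the two-group design, and the baselines remain two-group only.
* Plain PCA only; no robust or nonlinear variants.
* Simulation sizes in the test suite and acceptance script (20–100 seeds
  per regime, matrices up to 110 features) are chosen to characterise the
  stated regimes at desk scale while keeping the whole suite fast.
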