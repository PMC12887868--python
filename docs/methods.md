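# Methods

## Model

Each gene's expression vector `y` (length n, one entry per individual,
assumed already normalized — e.g. log2 quantile-normalized TPMs with
hidden-confounder correction done upstream) is modeled as

    y = 1·μ + g_cis + ε,    g_cis ~ N(0, G·Vg),    ε ~ N(0, I·Ve),

where `G` is the genetic relationship matrix (GRM) built from variants in
the gene's cis window with the standard allele-frequency standardization
`A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i))`. Missing
dosages are mean-imputed per variant before standardization, keeping the
sample size constant. The intercept is the only fixed effect.

The cis-expression component (cis-EC) is the BLUP
`û = Vg·G·(Vg·G + Ve·I)⁻¹·(y − μ̂)` at the REML estimates, with `μ̂` the
GLS intercept; the trans-expression component (trans-EC) is
`(y − μ̂) − û`, so the two components reconstruct the centered expression
exactly by construction. The trans-EC is a residual: it contains distal
genetic regulation *and* measurement noise; the method relies on the
association step, not the decomposition, to separate signal from noise in
it. "Cis-predicted expression" is `μ̂ + û`. Note that `μ̂` is the GLS
mean under the fitted covariance, not the arithmetic sample mean; the two
coincide only for exchangeable covariance.

Association of a component with a response (a phenotype, or a target
gene's expression in the e-trait mode) uses the kinship mixed model
`response = μ + β·x + g + e`, `g ~ N(0, K·σ_g²)`. Variance components are
estimated once per response (null model, no predictor) and held fixed for
every predictor test — the one-pass approximation used by EMMAX-style
association scans. Each test is a GLS fit with a Wald z statistic against
a normal reference; cis-EC and trans-EC are always tested separately,
never jointly. The approximation error of not re-estimating variance
components per predictor is bounded empirically by the type-I calibration
test (rejection rate at 0.05 must stay in [0.035, 0.065] under a
structured-kinship null).

Genes enter association testing only if their cis variance component is
significant: `cis_p < α/N` with `α = 0.05` and `N` the number of genes
(Bonferroni). The final score is `rank_product = sqrt(rank(p_cis) ·
rank(p_trans))` with average ranks on ties; results are sorted by
rank_product, ties broken by trans p-value then gene id, so output files
are byte-reproducible.

## Numerical choices

* **REML (per gene).** All computations run in the eigenbasis of `G`, so
  each likelihood/gradient evaluation is O(n) after one symmetric
  eigendecomposition. Updates are average-information steps; the first
  iteration and any fallback use EM; AI proposals below the variance floor
  are clamped to it, and a step that loses likelihood is halved toward the
  current iterate before falling back to EM. Convergence: |Δ log L| <
  1e-8, at most 100 iterations (the best iterate is returned with
  `converged = False` otherwise). Variances are floored at `1e-6 · var(y)`
  rather than zero so the BLUP system never becomes singular.
* **Boundary LRT.** `cis_p = ½·Pr(χ²₁ > LRT)` — the 50:50 mixture null
  appropriate for a variance component on its boundary; `LRT = 0` gives
  p = 0.5; p floored at 1e-300.
* **Null model (per response).** Profiled REML over the variance ratio
  δ = σ_g²/σ_e² on a log grid in [e⁻⁸, e⁸] refined by bounded Brent, with
  the δ = 0 boundary checked in closed form. Negative kinship eigenvalues
  within −1e-8 are clipped to zero; anything lower is an error.
* **Degenerate inputs.** Genes with no polymorphic cis variant get
  `cis_ec = 0`, `trans_ec = y − ȳ`, `cis_p = 1` and are flagged with
  `n_cis_variants = 0`; a zero-variance predictor yields a flagged record
  with `p = 1, β = 0`; a constant response or an empty sample
  intersection is an error. Per-gene failures are logged and skipped
  without aborting the chromosome.
* **Multiple testing.** q-values are Benjamini–Hochberg step-up adjusted
  p-values per component. Empirical-null local-FDR estimators are an
  alternative here; BH was chosen because it is deterministic,
  assumption-light, and monotone in p, and the q-value columns mean
  exactly that.
* **Window convention.** Coordinates are 1-based and inclusive; the cis
  window is `[max(1, start − extend), end + extend]` with `extend =
  100 kb` by default, symmetric around the gene body and strand-agnostic
  (whether "upstream/downstream" should be strand-relative is left open;
  a symmetric window contains the strand-aware one). MAF filter default
  0.01 — monomorphic sites break GRM standardization, so some floor is
  mandatory.
* **Parallelism.** Per-chromosome decomposition tasks are independent;
  `--ncor > 1` runs them in separate processes and the outputs are
  byte-identical to a serial run.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `extend` | 1e5 bp | cis window half-width; match the species' LD decay |
| `maf_min` | 0.01 | minor-allele-frequency floor for cis variants |
| `p_threshold` | 0.05 / n_genes | cis-heritability filter (Bonferroni) |
| `alpha` | 0.05 | family-wise level behind the default threshold |
| `min_n` | 30 | minimum non-missing individuals per response |
| stringent filter | p_cis < 1e-3, q_trans < 1e-3 | high-confidence candidate cut |

## The simulator

The generator emulates the statistical structure the method assumes, not
any particular organism:

* **Genotypes.** Ancestral allele frequencies uniform on (0.05, 0.5);
  subpopulation frequencies from the Balding–Nichols beta model at Fst
  `divergence` (default 0.1 across 2 subpopulations — strong structure of
  the kind crop panels show); haplotypes copy the previous variant's
  allele with probability `ld_decay` (default 0.5), an AR(1) LD mechanism
  that is crude but sufficient to create the shared-window confounding
  the rank product is meant to defeat. Kinship is the genome-wide GRM.
* **Expression.** Per gene, a cis value `Z·a` on standardized window
  dosages, rescaled so the in-sample variance ratio equals the requested
  `cis_h2` exactly, plus trans-edge contributions (a DAG, evaluated in
  topological order) and unit normal noise. Defaults: `cis_h2 = 0.3`, no
  edges. Confounder pairs share window variants and have correlated cis
  effect vectors (ρ = 0.9).
* **Phenotype.** A weighted sum of chosen genes' cis/trans/total
  components, plus a kinship-distributed polygenic term (sd 0.5) and
  Gaussian noise (sd 1.0).
* **Default population size** is n = 300 individuals, the scale of a
  typical re-sequenced diversity panel.

What the simulator does **not** emulate: realistic site-frequency spectra
and recombination maps (no coalescent), cyclic regulatory feedback,
expression count noise and normalization artifacts, hidden confounders of
the kind PEER removes, and assortative or family structure beyond the
two-subpopulation model. Passing the planted-recovery tests therefore
shows the estimator and the ranking behave as designed under the model's
own assumptions — not that real expression data meet those assumptions.

## Study sizes used by the test suite and acceptance script

Decomposition identity on 50 genes at n = 300; REML recovery at h² ∈
{0.1, 0.3, 0.5, 0.8}, n = 400, 200 cis variants, 50 replicates per level
(mean within ±0.07 of truth); LRT null calibration over 1000 replicates at
n = 300 (rejection rate in [0.02, 0.08] — the boundary test is
conservative-to-nominal); association null calibration over 2000 tests at
n = 300; planted-causal (trait) and planted-edge (e-trait) recovery over
25 replicates of 200-gene populations at n = 300, requiring the planted
gene at final rank 1 in ≥ 80% of replicates and, in the trait mode, a
strictly better median rank than the LD-linked confounder.

## Known limitations

* The EMMAX-style fixed-variance-component scan slightly mis-calibrates
  when a predictor explains a large variance share; exact per-predictor
  REML would be ~400× slower at transcriptome scale.
* Covariates are not supported in the association model (v1); correct for
  them upstream in the expression/phenotype preparation.
* No cross-validated prediction into held-out individuals, no joint
  cis+trans or multi-gene models, no colocalization.
* `cis_p` and the heritability filter assume the expression vector is
  approximately Gaussian after normalization; heavy-tailed genes inflate
  `Vg` estimates.
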