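# Methods

## Mixture model and fitting

Bulk beta values are modeled as convex combinations of K latent cell-type
methylomes: `Y = M Ω^T` with `Y` the m×n matrix of methylation fractions,
`M ∈ [0,1]^{m×K}` the cell-type methylation states and each row of
`Ω ∈ R^{n×K}` on the probability simplex (nonnegative, summing to one; a
`sub_simplex` option relaxes the sum to ≤ 1 for users who want an
"unexplained remainder" component).  This is the standard reference-free
deconvolution assumption: methylation is measured on a fraction scale, so
a mixture of cells yields the proportion-weighted average of their
methylomes.

Fitting is alternating least squares in which both half-steps are exact
minimizers of the Frobenius objective under their constraints:

* **Ω step.** For each sample, `min ‖y_i − M w‖²` over the simplex is a
  K-dimensional quadratic program.  The equality-constrained (sum-to-one)
  KKT solution is computed for all samples in one vectorized solve; only
  samples whose interior solution goes negative fall back to a per-sample
  active-set QP (exact for the PSD Gram matrix, ridge-regularized by
  1e-10).
* **M step.** Box-constrained least squares per probe, solved by cyclic
  coordinate descent over the K columns (four sweeps per outer
  iteration); each clipped update is the exact coordinate minimizer, so
  the objective never increases.

The objective trace is recorded per iteration and asserted non-increasing
in the test suite.  Iteration stops when the relative objective change
drops below `tol` (default 1e-6) or at `max_iter` (default 1000; a
non-converged fit is returned with `converged=False` and a warning).
Initialization is k-means on logit-betas over samples (memberships
softened to 0.9/0.1) plus random-Dirichlet restarts (default 5 total);
the best final objective wins.  Missing beta values are mean-imputed per
probe for factorization only; association testing keeps the original
missingness.

**Identifiability.** The factorization is unique only up to column
permutation, and only when the sampled proportions span the simplex (the
data's convex hull must pin the fitted vertices).  All comparisons to
simulation truth therefore use Hungarian matching on column correlations
(`match_columns`), and recovery claims are made at sample sizes where
hull coverage suffices (n ≥ 100 for K = 2–3 with uniform-Dirichlet
proportions).  With tightly concentrated proportions the decomposition is
not identifiable and no accuracy of `Ω` should be expected — only of the
reconstruction.

## Choosing the number of cell types

K is selected over a candidate grid (default 2…10) by bootstrapped
deviance.  For each candidate: fit on the full data; for each of
`n_boot` (default 10) bootstrap resamples of samples, re-fit `M` on the
resample (warm-started from the full fit, ≤ 25 iterations), fit the
out-of-bag samples' proportion rows against that fixed `M`, and score the
out-of-bag reconstruction with a Gaussian profile deviance

    dev = Σ_j n_oob · log( RSS_j / (n_oob − K + 1) ),

where `RSS_j` sums squared out-of-bag residuals of probe j.  The
`n_oob − K + 1` denominator is a degrees-of-freedom correction for the
K−1 free parameters each out-of-bag sample's proportion fit consumes;
without it the statistic is non-increasing in K by construction and
cannot select a finite model (the uncorrected form remains available via
`df_correct=False`).  Two design points matter:

* **Paired resamples.** The same bootstrap replicates are reused for
  every candidate K.  The deviance differences between neighboring K are
  orders of magnitude smaller than the between-resample variation, so an
  unpaired comparison is essentially random among K ≥ K_true.
* **In-bag re-fit of M.** Scoring out-of-bag data against an `M` fitted
  on the full data double-dips (the full fit has seen the out-of-bag
  noise) and systematically favors larger K.

Ties break toward smaller K.  On structureless data the corrected
deviance is non-decreasing beyond K = 2 and the smallest candidate wins.
Note that any genuine phenotype effect in the data (e.g. a tumor mean
shift on many CpGs) is itself low-rank structure and legitimately raises
the selected K; selection is agnostic to what the structure means.

## Per-CpG testing and the leakage problem

Within a stratum, each CpG is tested by OLS of its beta values on
intercept + tumor indicator + age (optional) + K−1 columns of `Ω`; the
column with the largest mean proportion is dropped (configurable) because
simplex rows are exactly collinear with the intercept.  The p-value is
the two-sided t-test on the tumor coefficient; `direction` is hyper/hypo
by its sign.  Samples missing a covariate are dropped from the model;
samples missing the CpG's beta are dropped probe-wise with `n_used`
recorded.  Constant-response probes and rank-deficient designs yield
flagged missing results rather than silent omissions; a stratum with
fewer than 3 residual degrees of freedom is an error.

A single pass of this procedure is biased: a genuine tumor/normal
methylation difference is (approximately) a rank-one term `δ·t^T` in `Y`,
and factorizing the raw matrix lets it leak into `Ω̂`.  The resulting
tumor-correlated error in the covariates inflates false positives on
unaffected CpGs — in simulations with 5% spiked probes the realized
false-discovery proportion at q < 0.01 reached 0.78 on unlucky seeds,
while testing against the true `Ω` gave 0.  `fit_adjusted_ewas` therefore
alternates: factorize, test, then re-factorize *excluding* the probes
currently significant at the q cutoff (at most half the probes, keeping
the least significant), and re-test; two extra rounds suffice.  Exclusion
is preferred over subtracting estimated effects because subtraction hits
a self-consistent wrong fixed point when the groups' cell compositions
differ by chance (the broad, slightly biased coefficients remove real
composition signal).  When tumors and normals differ only in composition,
the adjusted tests call nothing, nothing is excluded, and the proportions
retain their phenotype-associated component — exactly what adjustment is
for.

## Multiple testing

Storey q-values: `π̂0(λ) = #{p > λ}/(m(1−λ))` on the grid λ = 0.05, …,
0.95 (step 0.05), smoothed by a cubic polynomial evaluated at the largest
λ and clamped to (0, 1]; q-values are the step-up
`min_{j≥i} π̂0·m·p_(j)/j` on the sorted p-values.  Forcing λ = {0} gives
π̂0 = 1 and reproduces Benjamini–Hochberg exactly, which is the oracle
used in tests.  q-values are invariant to input order and monotone in p.

## DMGR calling

CpGs map to (gene, region) units from the parallel `UCSC_RefGene_Group`
annotation lists; duplicate pairs within a probe count once, and at most
the first two distinct genes per probe are kept (the annotation-extension
convention of assigning a CpG to up to two neighboring genes).  Probes
without gene annotation are reported unmapped.  An alternate mode groups
by CpG-island context instead (Island/Shore/Shelf/OpenSea), where every
probe maps.  A unit is a DMGR when the median q over its member CpGs with
valid q falls below the cutoff (default rule; median over *all* members,
not only significant ones) or, under `rule="any"`, when at least one
member is individually significant.  Direction is `+`/`-`/`-+` from the
signs of the significant members' tumor coefficients.  Per-stratum call
sets are intersected on (gene, region) keys; all 2^s − 1 exclusive
overlap classes are emitted for Venn/UpSet reporting.  Both rules are
monotone in the q cutoff.

## Downstream statistics

Region-class enrichment of a call set within its tested universe uses
Fisher's exact test (scipy) on the 2×2 table, the sample odds ratio
`(ad)/(bc)`, and a Woolf logit 95% CI with Haldane 0.5 correction applied
when any cell is zero; degenerate margins flag the OR undefined.
Methylation–expression coupling uses Spearman correlation (midrank ties)
per (probe, gene) pair on matched samples, with an exact permutation
p-value available for n ≤ 10, and a Bonferroni threshold α/#pairs always
derived from the package's own pair count.

## Synthetic data

The generator emulates normalized 450K-style data, not raw arrays:

* Cell methylomes: bimodal beta mixtures (low mode Beta(2,18) near 0.1,
  high mode Beta(18,2) near 0.9); a fraction `separation` of probes is
  discordant across cell types (opposite modes for K = 2), which is the
  source of identifiability.
* Proportions: Dirichlet, default α = (1,…,1) — uniform over the simplex.
  This reflects the wide composition variation of bulk tissue and gives
  the hull coverage identifiability needs.
* Tumor effect: a mean shift δ on spiked probes in tumor samples only — a
  phenotype effect separate from the mixture.  An alternative
  `tumor_alpha` mode shifts the tumor group's Dirichlet parameter
  instead, producing pure composition confounding with no methylome
  change, used to demonstrate the value of adjustment.
* Age: uniform on [35, 80] years, centered before applying per-probe
  slopes (beta units per year).
* Noise: logit-normal — Gaussian on the logit scale (sd `noise_sd`, a
  latent-scale quantity), mapped back through the inverse logit.  This
  keeps values in (0, 1) and mimics array marginals; it also makes the
  noise heteroscedastic in a realistic way.  With `noise_sd = 0` the
  identity `Y = M* Ω*^T` holds exactly.
* Expected values pushed outside [0, 1] by more than 0.2 before
  truncation trigger a warning (the effect size is probably
  unrealistic).
* The synthetic manifest lays genes out in contiguous probe blocks
  cycling through all six region classes, so gene-region collapsing is
  fully exercised; island relations cycle likewise.
* Expression: coupled genes are generated through a Gaussian copula
  against mean promoter methylation with latent correlation
  `2·sin(πρ/6)`, targeting a Spearman correlation of ρ; uncoupled genes
  are independent noise.

What the generator does **not** emulate: probe-type chemistry (Type
I/II), batch effects, copy-number-driven intensity artifacts, spatial
correlation of neighboring CpGs beyond shared gene blocks, and realistic
linkage between subtype labels and methylation (labels are assigned
round-robin).  Passing tests therefore demonstrate correctness of the
algorithms under the stated mixture model, not performance on any real
cohort.

## Analysis constants and filters

Probe filtering removes (1) probes with detection p > 1e-5 in strictly
more than 25% of samples, then (2) probes flagged by SNP,
cross-reactivity or sex-chromosome masks in the manifest; overlaps count
under the first rule, every probe lands in exactly one bucket, and the
filter is idempotent.  Masks are manifest booleans; published mask lists
are a packaging concern for the user.  Cohort assembly keeps tumors with
a usable subtype (Basal-like, Her2, LumA, LumB; Normal-like excluded),
dichotomizes stage as early (I/II) vs late (III/IV), retains
missing-stage tumors in totals but in no stratum, excludes tumors with
missing age from age-adjusted models (exclusion, not imputation), and
always retains all normals.  The significance cutoff is q < 0.01
(configurable); the detection threshold and sample fraction are exposed
as options.

## Simulation sizes and tolerances

The shipped studies run at desk scale, chosen as defaults: noiseless
recovery at m = 300, n = 400 (K = 2); K-recovery at m = 300, n = 150 over
25 replicates (candidates 2–5, 5 bootstrap replicates); FDR/power at
m = 2000, n = 100+100, 5% spiked probes, |δ| = 0.3, logit noise 0.1, over
20 replicates; composition-confounding contrast at m = 1500, n = 80+80;
gene-region recall at m = 720 (60 genes × 12 probes), 10 spiked units,
over 20 replicates.  Numerical tolerances: beta bounds enforced to 1e-9
(clamped within, error beyond); simplex rows to 1e-8; objective
monotonicity to 1e-9; IO round-trips to 1e-12.  Spike directions in the
shipped studies point away from the nearer beta boundary so expectations
stay inside [0, 1].

## Known limitations

* The deviance definition for K selection is this package's own; the
  method family's original software is not reproduced bit-for-bit, and
  the statistic is isolated behind one function so an alternative can be
  swapped in.
* OLS t-tests assume homoscedastic Gaussian residuals per CpG; beta
  values are heteroscedastic near the boundaries.  Bootstrap standard
  errors would be a natural extension.
* Estimated proportions enter the per-CpG models as if known;
  uncertainty in `Ω̂` is not propagated.
* With K over-specified, surplus components absorb noise; the adjusted
  tests tolerate this, but interpretation of individual components as
  cell types is not warranted without external validation.
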