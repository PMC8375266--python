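# Methods

## Overview

`smrwalk` couples two estimators of gene–disease relevance that use
disjoint information: a network classifier that exploits the tendency of
disease genes to cluster in interaction networks, and a summary-data
Mendelian randomization (SMR) test that exploits genetic variants as
instruments for gene expression. Both run on the same synthetic study so
every claim the package makes is checkable against planted ground truth.

## The SMR test

For gene *g* with top cis-eQTL SNP *z*, let `b_zy ± se_zy` be the SNP's
trait effect (GWAS) and `b_zx ± se_zx` its expression effect (eQTL), both
per copy of the same effect allele after harmonization. The Wald ratio
`b_xy = b_zy/b_zx` estimates the expression→trait effect under the
standard instrumental-variable assumptions: the SNP affects the trait only
through the gene's expression (no horizontal pleiotropy), is associated
with expression, and is independent of confounders. The Delta-method
variance assumes the two studies are sampled from independent cohorts
(cross-covariance zero) and that `se_zx/|b_zx|` is small enough for the
first-order expansion; the test statistic
`T_SMR = z_zy² z_zx²/(z_zy²+z_zx²)` is referred to a chi-square with 1 df.

Implementation notes:

- the variance is computed in the expanded form
  `se_zy²/b_zx² + b_zy² se_zx²/b_zx⁴`, which is exact at `b_zy = 0`;
- the chi-square tail uses `scipy.stats.chi2.sf` directly (never
  `1 − cdf`), keeping precision for p-values near machine epsilon;
- the single-sample 2SLS variance
  `var(y)(1−P²_xy)/(n·var(x)·P²_zy)` is exposed
  (`var_xy_single_sample`) for completeness but is not on the pipeline
  path, which is strictly two-sample;
- a `z²` underflow with one argument subnormal returns `T = 0` (the
  mathematically correct limit) instead of dividing zero by zero.

**Instrument selection.** One SNP per gene: the smallest eQTL p-value,
admitted only below `p_eqtl_max = 5e-8` (the conventional genome-wide
instrument threshold); ties break on the lexicographically smaller SNP id
so results are deterministic. **Multiple testing** is Bonferroni across
the genes actually tested at family-wise α = 0.05 (Benjamini–Hochberg
available via `correction="bh"`). No heterogeneity (HEIDI-style) test is
performed — a documented limitation: linkage of two causal variants can
masquerade as mediation and is not filtered here.

**Harmonization.** GWAS effects are sign-aligned to the eQTL effect
allele, resolving swapped and opposite-strand codings by complementing;
incompatible allele pairs are dropped with reason codes, and
strand-ambiguous SNPs (A/T, C/G) are dropped by default since they cannot
be aligned without allele-frequency matching. All exclusions are counted
and surface in the run manifest, so consecutive stage counts always
reconcile.

## The random-walk encoder

The optimizer is a derivative-free direct search: from the current point
`x`, draw `u ~ Uniform(−1,1)^n`, normalize to `u′ = u/‖u‖`, propose
`x₁ = x + λu′`, accept iff `f(x₁) < f(x)` strictly (ties rejected, which
also resets the failure counter), halve λ after `N` consecutive failures,
and stop when `λ < ε`. Consequences used by the tests: λ after `r` failed
rounds is exactly `λ₀/2^r` (binary-exact halving); the number of rounds
is at most `⌈log₂(λ₀/ε)⌉`; the best value is monotone in the evaluation
budget for a fixed seed because the random stream is consumed identically
up to truncation.

Defaults: `λ₀ = 1`, `ε = 1e−4`, `N = 30` failures per round,
`max_evals = 50,000` (a desk-scale budget; the result carries a
`truncated` flag when it binds), embedding dimension 16.

**Network objective.** The encoder fits per-gene vectors `X ∈ R^{|V|×dim}`
minimizing the off-diagonal adjacency reconstruction
`f(X) = Σ_{i<j} (A_ij − x_i·x_j)²` — the minimal objective consistent
with "encode the network so that interacting genes have similar
features". **Initialization** is the truncated eigendecomposition of `A`
(top-`dim` eigenpairs, columns scaled by √λ⁺), which the random walk then
refines; this is the classical warm start for low-rank symmetric
factorization, and it matters in practice: from a small random start the
direct search cannot traverse a ~4,000-dimensional landscape within any
reasonable budget, leaving the embedding uninformative, whereas the
spectral start puts it in the right basin and the walk measurably lowers
the objective from there. `init="uniform"` (uniform(−0.1, 0.1)) remains
available for studying the optimizer itself.

**RWR alternative.** `rwr_encode` gives each gene its stationary
random-walk-with-restart affinity to every seed gene (restart probability
0.3). Columns conserve probability mass (sum to 1 per seed). Its
limitation as a feature map: seed genes carry their own restart mass, so
features separate seeds from everything else more than module from
non-module; the reconstruction encoder treats all genes symmetrically and
is the default.

## Classification

Positives are the seed genes; negatives are drawn uniformly without
replacement from the unlabeled genes, matched in number to the positives.
Features are Z-scored with mean and population SD fitted on training rows
only — refit inside every cross-validation fold, so no statistics of
held-out genes leak into training (a guard test constructs a case where
deliberate leakage changes the AUC). The classifier is an RBF-kernel SVM
(`C = 1`, `γ = 1/dim`) solved by libsvm's SMO-type dual solver; the
contract is the continuous decision function, not the solver internals.

Evaluation is stratified 10-fold cross-validation; AUC is trapezoidal ROC
integration (identical to the Mann–Whitney pair statistic, which the
tests verify by brute-force pair counting) and AUPR is the step-function
precision–recall integral. Because a single negative draw makes these
metrics high-variance at n = 34 + 34, the reported numbers average over
10 independent negative resamplings (mean ± sd). The final model is
trained once on all labeled genes; novel genes are the unlabeled genes
with decision score > 0 (the margin midpoint — no printed cutoff exists
to match, and top-k would need an arbitrary k). Baselines (random forest,
Gaussian naive Bayes, an MLP back-propagation network, logistic
regression) run on identical folds through the same metric code path.

## The synthetic study

The generator emulates a two-sample GWAS–eQTL integration design at desk
scale, with defaults chosen to mirror the emulated analysis:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 240 | network size (kept: largest connected component) |
| `module_size` | 60 | planted dense disease module |
| `n_seed_genes` | 34 | known disease genes, sampled from the module |
| `n_causal_genes` | 45 | genes with a real expression→trait effect |
| `b_xy_causal` | 0.3 | that effect, in trait SD per expression SD |
| `n_snps_per_gene` | 10 | cis-instrument candidates per gene |
| `eqtl_effect_sd` | 0.05 | SD of ordinary cis-eQTL effects |
| `top_snp_scale` | 8 | top SNP's \|effect\| in units of `eqtl_effect_sd` |
| `n_gwas`, `n_eqtl` | 10,000 | cohort sizes (independent samples) |
| `maf_range` | (0.10, 0.45) | uniform MAF; 0 and 0.5 are rejected as degenerate |

Summary statistics are simulated directly at the level of estimates:
`b̂_zx = b_zx + N(0, se²_zx)` and `b̂_zy = b_xy·b_zx + N(0, se²_zy)` with
independent noise and the per-allele standard error `1/√(2p(1−p)n)`. One
SNP per gene gets a deterministic-magnitude inflated effect
(random sign) so instrument selection is non-degenerate and instruments
are strong, mirroring strongest-cis-SNP practice. In the joint simulation
the causal genes are drawn from the planted module, so the SMR-significant
and network-predicted sets overlap by construction — the analog of the
two evidence streams converging on the same biology.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: linkage disequilibrium between
SNPs (each SNP is an independent instrument here, so there is no
linkage-vs-pleiotropy confusion for SMR to mis-handle), case/control
ascertainment and the liability scale, population structure, winner's
curse in the GWAS, and the annotation noise of real interaction networks.
Calibration and power results transfer to real data only to the extent
those features are negligible.

## Pipeline reproducibility

One global seed fans out to per-stage sub-seeds through
`numpy.random.SeedSequence.spawn`, so stages are statistically
independent yet a re-run with the same config is byte-identical (floats
are written with `repr` round-trip precision and read back with
pandas' `float_precision="round_trip"`). The manifest records
outdir-relative artifact paths, per-stage counts and sub-seeds; the
`report` command prints the filter-step accounting (SNPs read → shared →
harmonized → instruments → significant; genes predicted; overlap), and
exclusion tallies exactly explain every count drop.

## Known limitations

- Single-instrument SMR only: no multi-SNP extension, no HEIDI, no
  colocalization, no LD reference.
- The network objective is a design choice; nothing guarantees it matches
  any particular published embedding. Both encoders are provided and
  documented rather than claimed exact.
- At 34 positives, cross-validated metrics remain noisy even after
  negative resampling; the sd in the CV report should always be read
  alongside the mean.
- The decision-score threshold 0 for "novel gene" calls is the SVM margin
  convention, not a calibrated probability cutoff.
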