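# smrwalk

Disease-gene prioritization that fuses two complementary lines of
evidence, built for statistical geneticists working with GWAS and eQTL
**summary statistics** (no individual-level data required):

1. **Network machine learning (SVM-RW).** A weighted gene interaction
   network is encoded into per-gene feature vectors by a random-walk
   stochastic optimizer, and a support vector machine trained on known
   disease ("seed") genes versus sampled negatives ranks every other gene.
2. **Summary-data Mendelian randomization (SMR).** For each gene, its
   strongest cis-eQTL SNP serves as an instrumental variable to test
   whether the gene's expression mediates a SNP–trait association.

Genes flagged by both routes — predicted by the classifier *and*
significant under SMR — are the prioritized candidates. Because the real
cohort-scale datasets such analyses consume are not redistributable, the
package ships a first-class synthetic-data generator with planted ground
truth (a scale-free network with a dense disease module, and two-sample
summary statistics with known expression-mediated effects), so the entire
pipeline is testable end-to-end on a desk.

## The statistics

With `b_zy` the SNP→trait effect from a GWAS and `b_zx` the SNP→expression
effect from an independent eQTL study, the Wald-ratio (2SLS) estimate of
the expression→trait effect is

```
b_xy = b_zy / b_zx
```

Its sampling variance by the Delta method (cross-covariance zero in the
two-sample design) is

```
var(b_xy) ≈ (b_zy²/b_zx²)·(se_zx²/b_zx² + se_zy²/b_zy²)
```

and significance is tested with

```
T_SMR = z_zy² z_zx² / (z_zy² + z_zx²)  ~  χ²(1 df)
```

where `z = b/se` in each study. `T_SMR` is symmetric, bounded by the
smaller of the two single-study chi-squares, and approaches the GWAS
chi-square as the instrument becomes perfect.

The network encoder minimizes the adjacency-reconstruction objective
`f(X) = Σ_{i<j} (A_ij − x_i·x_j)²` with a derivative-free random walk:
steps of length λ in uniformly random directions, strict-improvement
acceptance, λ halved after N consecutive failures, termination when
λ < ε. A random-walk-with-restart (RWR) affinity encoder is included as
the propagation-style alternative (`--encoder rwr`).

## Worked example

```python
from smrwalk import (SimulationConfig, RwConfig, simulate_all, run_smr,
                     encode_network, cross_validate_resampled, t_smr)

t, p = t_smr(3.0, 4.0)        # T_SMR = 5.76, p = 0.0164

cfg = SimulationConfig(seed=1)            # the default study conditions
gwas, eqtl, net, truth = simulate_all(cfg)
# 2400 GWAS SNPs, 2400 eQTL pairs, 240-gene network, 34 seed genes

results = run_smr(gwas, eqtl)             # 240 genes tested, 43 significant
results.significant_genes()

emb = encode_network(net, RwConfig(dim=16, seed=2))
rep = cross_validate_resampled(emb, net, k=10, n_resamplings=10, seed=3)
# mean 10-fold AUC 0.930 +/- 0.028, AUPR 0.931
```

The SMR table reports, per gene, the top instrument SNP, `b_xy`, its
standard error, `T_SMR`, the raw and Bonferroni-adjusted p-values, and the
significance flag; e.g. gene `G0005` above recovers
`b_xy = 0.303 (se 0.040)` against a planted true effect of `0.3`.

Or from the shell, the whole pipeline in one command:

```bash
smrwalk run-all --outdir demo_run --seed 1
smrwalk report demo_run/manifest.json
```

which writes the simulated inputs, the embedding, the cross-validation
report, the novel-gene predictions, the SMR table, the overlap of the two
gene sets and a manifest with per-stage counts and seeds. Re-running with
the same config reproduces byte-identical outputs.

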