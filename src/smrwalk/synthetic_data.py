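"""Synthetic two-sample summary statistics and gene networks with known
ground truth.

The generator emulates, at desk scale, the inputs of a GWAS-eQTL
integration study: a scale-free gene interaction network with a planted
dense "disease module" containing the seed (known disease) genes, and
per-SNP summary statistics from two independent cohorts.  Summary
statistics are simulated directly at the level of estimates and standard
errors (no individual-level genotypes): for each gene, cis-SNP eQTL
effects are drawn from a normal distribution, one top SNP per gene is
given an inflated effect so instrument selection is non-degenerate, and
GWAS effects are ``b_xy * b_zx`` plus independent sampling noise.  The
per-allele standard error uses the standard approximation
``1 / sqrt(2 p (1 - p) n)`` at minor-allele frequency ``p`` and sample
size ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_summary import (EqtlRecord, GwasRecord, write_eqtl, write_gene_list,
                         write_gwas, write_edge_list)
from .rw_encoder import GeneNetwork

__all__ = ["SimulationConfig", "GroundTruth", "simulate_summary_stats",
           "simulate_network", "simulate_all", "write_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    The defaults mirror the scale of the emulated analysis: a 240-gene
    network with a planted module of 60 genes containing 34 seed genes,
    45 genes with a genuine expression-mediated trait effect of
    ``b_xy_causal = 0.3``, 10 cis-SNPs per gene, and two independent
    cohorts of 10,000 samples each.
    """

    n_genes: int = 240
    n_snps_per_gene: int = 10
    n_causal_genes: int = 45
    b_xy_causal: float = 0.3
    eqtl_effect_sd: float = 0.05
    #: the per-gene top eQTL SNP's |effect| in units of ``eqtl_effect_sd``
    top_snp_scale: float = 8.0
    n_gwas: int = 10_000
    n_eqtl: int = 10_000
    maf_range: tuple[float, float] = (0.1, 0.45)
    network_model: str = "barabasi_albert"
    module_size: int = 60
    module_edge_prob: float = 0.3
    n_seed_genes: int = 34
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 0.5 "
                             "(0 and 0.5 are degenerate)")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes exceeds n_genes")
        if self.module_size > self.n_genes:
            raise ValueError("module_size exceeds n_genes")
        if self.n_seed_genes > self.module_size:
            raise ValueError("n_seed_genes exceeds module_size")
        if not 0.0 <= self.module_edge_prob <= 1.0:
            raise ValueError("module_edge_prob must be in [0, 1]")
        if self.network_model not in ("barabasi_albert", "erdos_renyi"):
            raise ValueError(f"unknown network_model {self.network_model!r}")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests downstream."""

    causal_genes: set[str] = field(default_factory=set)
    true_b_zx: dict[tuple[str, str], float] = field(default_factory=dict)
    true_b_xy: dict[str, float] = field(default_factory=dict)
    module_genes: set[str] = field(default_factory=set)
    seed_genes: set[str] = field(default_factory=set)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            causal_genes=self.causal_genes | other.causal_genes,
            true_b_zx={**self.true_b_zx, **other.true_b_zx},
            true_b_xy={**self.true_b_xy, **other.true_b_xy},
            module_genes=self.module_genes | other.module_genes,
            seed_genes=self.seed_genes | other.seed_genes)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_summary_stats(cfg: SimulationConfig,
                           gene_ids: list[str] | None = None,
                           causal_genes: set[str] | None = None,
                           ) -> tuple[list[GwasRecord], list[EqtlRecord], GroundTruth]:
    """Simulate two-sample GWAS and eQTL summary statistics.

    For every gene, ``n_snps_per_gene`` cis-SNPs get true eQTL effects
    ``b_zx ~ N(0, eqtl_effect_sd^2)`` except the first ("top") SNP whose
    |effect| is fixed at ``top_snp_scale * eqtl_effect_sd`` with random
    sign.  Estimates add independent noise at the per-allele SE implied
    by the cohort sizes, so GWAS and eQTL errors are uncorrelated
    (two-sample design).  Causal genes (``true_b_xy = b_xy_causal``) are
    drawn at random unless supplied.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    genes = list(gene_ids) if gene_ids is not None else _gene_names(cfg.n_genes)
    if causal_genes is None:
        causal_genes = set(rng.choice(genes, size=cfg.n_causal_genes,
                                      replace=False))
    else:
        causal_genes = set(causal_genes)

    gwas: list[GwasRecord] = []
    eqtl: list[EqtlRecord] = []
    truth = GroundTruth(causal_genes=causal_genes)
    lo, hi = cfg.maf_range
    for gi, gene in enumerate(genes):
        b_xy = cfg.b_xy_causal if gene in causal_genes else 0.0
        truth.true_b_xy[gene] = b_xy
        for j in range(cfg.n_snps_per_gene):
            snp = f"rs{gi * 1000 + j}"
            maf = rng.uniform(lo, hi)
            if j == 0:
                b_zx = cfg.top_snp_scale * cfg.eqtl_effect_sd * rng.choice([-1.0, 1.0])
            else:
                b_zx = rng.normal(0.0, cfg.eqtl_effect_sd)
            truth.true_b_zx[(snp, gene)] = b_zx
            var_g = 2.0 * maf * (1.0 - maf)
            se_zx = 1.0 / np.sqrt(var_g * cfg.n_eqtl)
            se_zy = 1.0 / np.sqrt(var_g * cfg.n_gwas)
            bhat_zx = b_zx + rng.normal(0.0, se_zx)
            bhat_zy = b_xy * b_zx + rng.normal(0.0, se_zy)
            p_zx = 2.0 * stats.norm.sf(abs(bhat_zx / se_zx))
            p_zy = 2.0 * stats.norm.sf(abs(bhat_zy / se_zy))
            eqtl.append(EqtlRecord(
                snp_id=snp, gene_id=gene, effect_allele="A", other_allele="G",
                beta_zx=bhat_zx, se_zx=se_zx, p_zx=max(p_zx, 1e-300)))
            gwas.append(GwasRecord(
                snp_id=snp, effect_allele="A", other_allele="G", eaf=maf,
                beta_zy=bhat_zy, se_zy=se_zy, p_zy=max(p_zy, 1e-300),
                n=cfg.n_gwas, chrom="1", pos=(gi + 1) * 1_000_000 + j * 1000))
    return gwas, eqtl, truth


def simulate_network(cfg: SimulationConfig) -> tuple[GeneNetwork, GroundTruth]:
    """Simulate a gene interaction network with a planted disease module.

    The base graph is scale-free (Barabasi-Albert, m=2) or Erdos-Renyi at
    matched density; ``module_size`` genes are then densified by adding
    edges among them with probability ``module_edge_prob``; seed genes
    are sampled from the module.  Only the largest connected component is
    kept.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_genes
    genes = _gene_names(n)
    nx_seed = int(rng.integers(2**31 - 1))
    if cfg.network_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, m=2, seed=nx_seed)
    else:
        g = nx.erdos_renyi_graph(n, p=4.0 / n, seed=nx_seed)
    base_density = nx.density(g)
    if cfg.module_edge_prob < base_density:
        import warnings
        warnings.warn("module_edge_prob below base density: "
                      "planted signal absent", stacklevel=2)
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    module = sorted(rng.choice(genes, size=cfg.module_size, replace=False))
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.uniform() < cfg.module_edge_prob:
                g.add_edge(module[i], module[j])
    nx.set_edge_attributes(g, 1.0, "weight")
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    module_kept = [m for m in module if m in comp]
    seeds = set(rng.choice(module_kept, size=cfg.n_seed_genes, replace=False))
    net = GeneNetwork(graph=g, seed_genes=frozenset(seeds))
    truth = GroundTruth(module_genes=set(module_kept), seed_genes=seeds)
    return net, truth


def simulate_all(cfg: SimulationConfig
                 ) -> tuple[list[GwasRecord], list[EqtlRecord],
                            GeneNetwork, GroundTruth]:
    """Joint simulation: causal genes are drawn from the planted module,
    so network structure and expression-mediated effects agree and the
    SMR-significant and network-predicted gene sets overlap by design."""
    net, net_truth = simulate_network(cfg)
    rng = np.random.default_rng([cfg.seed, 3])
    module = sorted(net_truth.module_genes)
    n_from_module = min(cfg.n_causal_genes, len(module))
    causal = set(rng.choice(module, size=n_from_module, replace=False))
    if n_from_module < cfg.n_causal_genes:
        rest = sorted(set(net.nodes) - set(module))
        causal |= set(rng.choice(rest, size=cfg.n_causal_genes - n_from_module,
                                 replace=False))
    gwas, eqtl, stats_truth = simulate_summary_stats(
        cfg, gene_ids=net.nodes, causal_genes=causal)
    return gwas, eqtl, net, net_truth.merged_with(stats_truth)


def write_dataset(outdir, gwas, eqtl, net: GeneNetwork,
                  truth: GroundTruth) -> dict[str, str]:
    """Write the three standard inputs plus ground-truth TSVs; returns a
    name -> path manifest fragment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": str(outdir / "gwas.ma"),
        "eqtl": str(outdir / "eqtl.tsv"),
        "network": str(outdir / "network.tsv"),
        "seed_genes": str(outdir / "seed_genes.txt"),
        "truth_genes": str(outdir / "truth_genes.tsv"),
        "truth_snps": str(outdir / "truth_snps.tsv"),
    }
    write_gwas(gwas, paths["gwas"], dialect="ma")
    write_eqtl(eqtl, paths["eqtl"])
    write_edge_list([(u, v, d.get("weight", 1.0))
                     for u, v, d in net.graph.edges(data=True)],
                    paths["network"])
    write_gene_list(sorted(net.seed_genes), paths["seed_genes"])
    genes = sorted(truth.true_b_xy) or sorted(truth.module_genes)
    pd.DataFrame({
        "gene": genes,
        "true_b_xy": [truth.true_b_xy.get(g, 0.0) for g in genes],
        "causal": [int(g in truth.causal_genes) for g in genes],
        "module": [int(g in truth.module_genes) for g in genes],
        "seed_gene": [int(g in truth.seed_genes) for g in genes],
    }).to_csv(paths["truth_genes"], sep="\t", index=False)
    keys = sorted(truth.true_b_zx)
    pd.DataFrame({
        "SNP": [k[0] for k in keys],
        "gene": [k[1] for k in keys],
        "true_b_zx": [truth.true_b_zx[k] for k in keys],
    }).to_csv(paths["truth_snps"], sep="\t", index=False)
    return paths
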