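"""Summary-data Mendelian randomization (SMR).

Tests, gene by gene, whether expression mediates a SNP-trait association
using only summary statistics from two independent studies.  The
instrumental-variable (Wald ratio) estimate of the expression-on-trait
effect is

    b_xy = b_zy / b_zx ,

with the GWAS effect ``b_zy`` and the eQTL effect ``b_zx`` taken at the
gene's strongest cis-eQTL SNP.  Under the two-sample design the sampling
errors of the two effects are independent, so the Delta-method variance
of the ratio reduces to

    var(b_xy) ~ (b_zy^2 / b_zx^2) (se_zx^2/b_zx^2 + se_zy^2/b_zy^2)
             = se_zy^2/b_zx^2 + b_zy^2 se_zx^2 / b_zx^4 ,

(the expanded form is safe at b_zy = 0) and the test statistic

    T_SMR = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2)  ~  chi^2_1

combines the two z-statistics.  No heterogeneity (HEIDI-style) filtering
is performed; see the package documentation for this limitation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_summary import EqtlRecord, GwasRecord, HarmonizedPair, harmonize

logger = logging.getLogger(__name__)

__all__ = ["SmrConfig", "SmrResult", "SingleSampleInputs", "wald_ratio",
           "var_xy_single_sample", "var_xy_delta", "t_smr",
           "select_instrument", "run_smr", "overlap_genes", "smr_table"]


@dataclass(frozen=True)
class SmrConfig:
    """Instrument-selection and multiple-testing settings."""

    p_eqtl_max: float = 5e-8
    correction: str = "bonferroni"  # or "bh"
    alpha: float = 0.05
    drop_ambiguous: bool = True
    #: optional cis-window in bp around the gene; applied only when both
    #: SNP positions and a gene-position map are available
    cis_window: int = 1_000_000


@dataclass(frozen=True)
class SingleSampleInputs:
    """Ingredients of the single-sample 2SLS sampling variance: trait and
    exposure variances, sample size, and the variance fractions of the
    trait explained by the exposure (p2_xy) and by the variant (p2_zy)."""

    var_y: float
    var_x: float
    n: int
    p2_xy: float
    p2_zy: float

    def __post_init__(self):
        if self.var_y <= 0 or self.var_x <= 0:
            raise ValueError("variances must be positive")
        if not (0 <= self.p2_xy <= 1 and 0 <= self.p2_zy < 1):
            raise ValueError("variance fractions must be in [0, 1]; "
                             "p2_zy = 1 excluded")


@dataclass(frozen=True)
class SmrResult:
    gene_id: str
    top_snp: str
    b_xy: float
    var_xy: float
    t_smr: float
    p_smr: float
    p_adj: float
    significant: bool
    method: str = "two_sample"


def wald_ratio(beta_zy: float, beta_zx: float) -> float:
    """Instrumental-variable (2SLS/Wald) estimate b_zy / b_zx."""
    if beta_zx == 0:
        raise ZeroDivisionError("undefined instrument: beta_zx = 0")
    return beta_zy / beta_zx


def var_xy_single_sample(inp: SingleSampleInputs) -> float:
    """Single-sample 2SLS sampling variance,
    ``var(y) (1 - p2_xy) / (n var(x) p2_zy)``.

    Exposed for completeness; the pipeline's operative path is the
    two-sample Delta variance (:func:`var_xy_delta`).
    """
    if inp.p2_zy == 0:
        raise ZeroDivisionError("p2_zy = 0 gives infinite variance")
    return (inp.var_y * (1.0 - inp.p2_xy)) / (inp.n * inp.var_x * inp.p2_zy)


def var_xy_delta(beta_zx: float, se_zx: float,
                 beta_zy: float, se_zy: float) -> float:
    """Two-sample Delta-method variance of the Wald ratio.

    Computed in the algebraically expanded form
    ``se_zy^2/b_zx^2 + b_zy^2 se_zx^2/b_zx^4`` so ``beta_zy = 0`` is safe;
    the cross-covariance term is zero because the cohorts are independent.
    """
    if beta_zx == 0:
        raise ZeroDivisionError("undefined instrument: beta_zx = 0")
    bzx2 = beta_zx * beta_zx
    return se_zy * se_zy / bzx2 + beta_zy * beta_zy * se_zx * se_zx / (bzx2 * bzx2)


def t_smr(z_zy: float, z_zx: float) -> tuple[float, float]:
    """SMR test statistic and its chi-square(1 df) upper-tail p-value.

    ``T = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2)``; symmetric in its arguments
    and bounded by min(z_zy^2, z_zx^2), approaching the GWAS chi-square
    as the instrument becomes perfect.  The tail is computed with
    ``chi2.sf`` (no 1-CDF subtraction) so tiny p-values keep precision.
    """
    if z_zy == 0.0 and z_zx == 0.0:
        raise ZeroDivisionError("t_smr undefined at z_zy = z_zx = 0")
    a = z_zy * z_zy
    b = z_zx * z_zx
    t = a * b / (a + b) if a + b > 0.0 else 0.0  # guards z**2 underflow
    return t, float(stats.chi2.sf(t, df=1))


def select_instrument(pairs: Sequence[HarmonizedPair], gene: str,
                      p_eqtl_max: float = 5e-8) -> HarmonizedPair | None:
    """The gene's top cis-eQTL SNP (smallest eQTL p), returned only if it
    passes the instrument threshold; ties break on the smaller SNP id."""
    candidates = [p for p in pairs if p.gene_id == gene]
    if not candidates:
        return None
    best = min(candidates, key=lambda p: (p.p_zx, p.snp_id))
    return best if best.p_zx <= p_eqtl_max else None


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "bh":
        from statsmodels.stats.multitest import multipletests
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction {method!r}")


def run_smr(gwas: Sequence[GwasRecord], eqtl: Sequence[EqtlRecord],
            cfg: SmrConfig = SmrConfig(),
            gene_pos: Mapping[str, int] | None = None) -> "SmrResultList":
    """Full SMR pass: harmonize, select one instrument per gene, test,
    and correct across the genes actually tested.

    Returns every tested gene's result (significant or not); the returned
    list carries filter-step counts in ``.counts`` for reporting.
    """
    pairs = harmonize(gwas, eqtl, drop_ambiguous=cfg.drop_ambiguous)
    counts = {
        "gwas_snps": len({g.snp_id for g in gwas}),
        "eqtl_pairs": len(eqtl),
        "shared_snps": len({p.snp_id for p in pairs}),
        "harmonized_pairs": len(pairs),
    }
    counts.update({f"excluded_{k}": v for k, v in pairs.exclusions.items()})
    if gene_pos is not None:
        pairs = [p for p in pairs
                 if p.pos is None or p.gene_id not in gene_pos
                 or abs(p.pos - gene_pos[p.gene_id]) <= cfg.cis_window]
        counts["cis_pairs"] = len(pairs)
    if not pairs:
        warnings.warn("no SNPs shared between GWAS and eQTL inputs",
                      stacklevel=2)
        out = SmrResultList()
        out.counts = counts
        return out

    genes = sorted({p.gene_id for p in pairs})
    by_gene: dict[str, list[HarmonizedPair]] = {g: [] for g in genes}
    for p in pairs:
        by_gene[p.gene_id].append(p)
    rows = []
    for gene in genes:
        inst = select_instrument(by_gene[gene], gene, cfg.p_eqtl_max)
        if inst is None:
            continue
        b_xy = wald_ratio(inst.beta_zy, inst.beta_zx)
        v_xy = var_xy_delta(inst.beta_zx, inst.se_zx, inst.beta_zy, inst.se_zy)
        t, p = t_smr(inst.z_zy, inst.z_zx)
        rows.append((gene, inst.snp_id, b_xy, v_xy, t, p))
    counts["genes_tested"] = len(rows)
    if not rows:
        out = SmrResultList()
        out.counts = counts
        return out
    p_raw = np.array([r[5] for r in rows])
    p_adj = _adjust(p_raw, cfg.correction)
    results = SmrResultList(
        SmrResult(gene_id=g, top_snp=s, b_xy=b, var_xy=v, t_smr=t,
                  p_smr=p, p_adj=float(pa), significant=bool(pa <= cfg.alpha))
        for (g, s, b, v, t, p), pa in zip(rows, p_adj))
    counts["significant_genes"] = sum(r.significant for r in results)
    results.counts = counts
    return results


class SmrResultList(list):
    """List of :class:`SmrResult` with per-stage ``counts`` attached."""

    counts: dict[str, int]

    def __init__(self, items=()):
        super().__init__(items)
        self.counts = {}

    def significant_genes(self) -> set[str]:
        return {r.gene_id for r in self if r.significant}


def smr_table(results: Sequence[SmrResult]) -> pd.DataFrame:
    """Tabular view with the standard output columns."""
    return pd.DataFrame({
        "gene": [r.gene_id for r in results],
        "snp": [r.top_snp for r in results],
        "b_xy": [r.b_xy for r in results],
        "se_xy": [float(np.sqrt(r.var_xy)) for r in results],
        "t_smr": [r.t_smr for r in results],
        "p_smr": [r.p_smr for r in results],
        "p_adj": [r.p_adj for r in results],
        "significant": [int(r.significant) for r in results]})


def overlap_genes(smr_sig: set[str], svm_pred: set[str]
                  ) -> tuple[set[str], float]:
    """Intersection of the SMR-significant and classifier-predicted gene
    sets, with the Jaccard index (0 for two empty sets)."""
    smr_sig, svm_pred = set(smr_sig), set(svm_pred)
    inter = smr_sig & svm_pred
    union = smr_sig | svm_pred
    return inter, (len(inter) / len(union)) if union else 0.0
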