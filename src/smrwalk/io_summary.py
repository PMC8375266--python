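"""Readers, writers and allele harmonization for two-sample summary statistics.

GWAS summary statistics follow the COJO ``.ma`` dialect by default
(``SNP A1 A2 freq b se p N``), the de-facto exchange format for
summary-data Mendelian randomization tools.  A ``generic-tsv`` dialect
accepts any tab-delimited file whose header carries the canonical column
names.  eQTL summary statistics are tab-delimited with one row per
(SNP, gene) pair.  All validation is row-level and non-fatal: dirty rows
are skipped and counted, never raised, because real summary files are
dirty.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GwasRecord",
    "EqtlRecord",
    "HarmonizedPair",
    "RecordList",
    "FormatError",
    "read_gwas",
    "write_gwas",
    "read_eqtl",
    "write_eqtl",
    "read_gene_list",
    "write_gene_list",
    "read_edge_list",
    "write_edge_list",
    "harmonize",
]

#: allele pairs that cannot be strand-resolved without frequency matching
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
_EQTL_COLUMNS = ["SNP", "gene", "A1", "A2", "b", "se", "p"]


class FormatError(ValueError):
    """A mandatory column is missing or a header does not match the dialect."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with the trait from a GWAS.

    ``beta_zy``/``se_zy`` are the per-allele effect and its standard
    error with respect to ``effect_allele``; ``z`` is their ratio.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_zy: float
    se_zy: float
    p_zy: float
    n: int
    chrom: str | None = None
    pos: int | None = None

    @property
    def z(self) -> float:
        return self.beta_zy / self.se_zy


@dataclass(frozen=True)
class EqtlRecord:
    """One SNP's association with one gene's expression from an eQTL study."""

    snp_id: str
    gene_id: str
    effect_allele: str
    other_allele: str
    beta_zx: float
    se_zx: float
    p_zx: float

    @property
    def z(self) -> float:
        return self.beta_zx / self.se_zx


@dataclass(frozen=True)
class HarmonizedPair:
    """A (SNP, gene) pair with the GWAS effect sign-aligned to the eQTL
    effect allele, so both betas refer to the same allele."""

    snp_id: str
    gene_id: str
    beta_zy: float
    se_zy: float
    n_gwas: int
    beta_zx: float
    se_zx: float
    p_zx: float
    flipped: bool
    pos: int | None = None

    @property
    def z_zy(self) -> float:
        return self.beta_zy / self.se_zy

    @property
    def z_zx(self) -> float:
        return self.beta_zx / self.se_zx


class RecordList(list):
    """A list of records that also carries row-level exclusion accounting.

    ``n_skipped`` counts rows dropped during parsing; ``exclusions`` maps
    reason codes to counts (used by :func:`harmonize`).
    """

    def __init__(self, items: Iterable = (), n_skipped: int = 0,
                 exclusions: Counter | None = None):
        super().__init__(items)
        self.n_skipped = n_skipped
        self.exclusions: Counter = exclusions if exclusions is not None else Counter()


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def read_gwas(path, dialect: str = "ma") -> RecordList:
    """Read GWAS summary statistics.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited file with a header line.
    dialect
        ``"ma"`` for the COJO column order ``SNP A1 A2 freq b se p N``;
        ``"generic-tsv"`` for a header with canonical names
        (``snp_id effect_allele other_allele eaf beta se p n`` plus
        optional ``chrom``/``pos``).

    Rows with non-numeric effect/SE, non-positive SE, p outside (0, 1]
    or equal alleles are skipped and counted in ``.n_skipped``.
    """
    path = Path(path)
    if dialect == "ma":
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
        _require_columns(df, _MA_COLUMNS, path)
        df = df.rename(columns={
            "SNP": "snp_id", "A1": "effect_allele", "A2": "other_allele",
            "freq": "eaf", "b": "beta", "N": "n"})
    elif dialect == "generic-tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        _require_columns(
            df, ["snp_id", "effect_allele", "other_allele", "eaf",
                 "beta", "se", "p", "n"], path)
    else:
        raise ValueError(f"unknown GWAS dialect: {dialect!r}")

    has_pos = "chrom" in df.columns and "pos" in df.columns
    records: list[GwasRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            beta = float(row.beta)
            se = float(row.se)
            p = float(row.p)
            n = int(row.n)
            eaf = float(row.eaf)
        except (TypeError, ValueError):
            skipped += 1
            continue
        a1 = str(row.effect_allele).upper()
        a2 = str(row.other_allele).upper()
        if not (se > 0) or not (0 < p <= 1) or a1 == a2 or not (0 <= eaf <= 1):
            skipped += 1
            continue
        records.append(GwasRecord(
            snp_id=str(row.snp_id), effect_allele=a1, other_allele=a2,
            eaf=eaf, beta_zy=beta, se_zy=se, p_zy=p, n=n,
            chrom=str(row.chrom) if has_pos else None,
            pos=int(row.pos) if has_pos else None))
    if skipped:
        logger.warning("read_gwas(%s): skipped %d invalid row(s)", path, skipped)
    return RecordList(records, n_skipped=skipped)


def write_gwas(records: Iterable[GwasRecord], path, dialect: str = "ma") -> None:
    """Write GWAS records; exact round-trip with :func:`read_gwas`."""
    records = list(records)
    if dialect == "ma":
        df = pd.DataFrame({
            "SNP": [r.snp_id for r in records],
            "A1": [r.effect_allele for r in records],
            "A2": [r.other_allele for r in records],
            "freq": [repr(float(r.eaf)) for r in records],
            "b": [repr(float(r.beta_zy)) for r in records],
            "se": [repr(float(r.se_zy)) for r in records],
            "p": [repr(float(r.p_zy)) for r in records],
            "N": [r.n for r in records]})
    elif dialect == "generic-tsv":
        df = pd.DataFrame({
            "snp_id": [r.snp_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [repr(float(r.eaf)) for r in records],
            "beta": [repr(float(r.beta_zy)) for r in records],
            "se": [repr(float(r.se_zy)) for r in records],
            "p": [repr(float(r.p_zy)) for r in records],
            "n": [r.n for r in records]})
    else:
        raise ValueError(f"unknown GWAS dialect: {dialect!r}")
    df.to_csv(path, sep="\t", index=False)


def read_eqtl(path) -> RecordList:
    """Read cis-eQTL summary statistics (``SNP gene A1 A2 b se p``).

    Duplicate (SNP, gene) keys are a hard error; invalid rows are
    skipped and counted as in :func:`read_gwas`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, _EQTL_COLUMNS, path)
    dup = df.duplicated(subset=["SNP", "gene"], keep=False)
    if dup.any():
        key = df.loc[dup, ["SNP", "gene"]].iloc[0].tolist()
        raise FormatError(f"{path}: duplicate (SNP, gene) key {tuple(key)}")
    records: list[EqtlRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            beta = float(row.b)
            se = float(row.se)
            p = float(row.p)
        except (TypeError, ValueError):
            skipped += 1
            continue
        a1 = str(row.A1).upper()
        a2 = str(row.A2).upper()
        if not (se > 0) or not (0 < p <= 1) or a1 == a2:
            skipped += 1
            continue
        records.append(EqtlRecord(
            snp_id=str(row.SNP), gene_id=str(row.gene), effect_allele=a1,
            other_allele=a2, beta_zx=beta, se_zx=se, p_zx=p))
    if skipped:
        logger.warning("read_eqtl(%s): skipped %d invalid row(s)", path, skipped)
    return RecordList(records, n_skipped=skipped)


def write_eqtl(records: Iterable[EqtlRecord], path) -> None:
    records = list(records)
    df = pd.DataFrame({
        "SNP": [r.snp_id for r in records],
        "gene": [r.gene_id for r in records],
        "A1": [r.effect_allele for r in records],
        "A2": [r.other_allele for r in records],
        "b": [repr(float(r.beta_zx)) for r in records],
        "se": [repr(float(r.se_zx)) for r in records],
        "p": [repr(float(r.p_zx)) for r in records]})
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; ``#`` starts a comment."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_edge_list(path) -> list[tuple[str, str, float]]:
    """STRING-export-style edge list: ``geneA geneB weight`` (TSV, header)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["geneA", "geneB", "weight"], path)
    return [(str(a), str(b), float(w))
            for a, b, w in zip(df["geneA"], df["geneB"], df["weight"])]


def write_edge_list(edges: Iterable[tuple[str, str, float]], path) -> None:
    edges = list(edges)
    df = pd.DataFrame(edges, columns=["geneA", "geneB", "weight"])
    df["weight"] = [repr(float(w)) for _, _, w in edges]
    df.to_csv(path, sep="\t", index=False)


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs read the same on both strands and cannot be
    safely aligned between studies without allele-frequency matching."""
    return _COMPLEMENT.get(a1) == a2


def harmonize(gwas: Sequence[GwasRecord], eqtl: Sequence[EqtlRecord],
              drop_ambiguous: bool = True) -> RecordList:
    """Align GWAS effects to the eQTL effect allele for every SNP present
    in both studies.

    For each eQTL (SNP, gene) row with a matching GWAS SNP:

    * same allele orientation -> kept as-is;
    * swapped alleles (GWAS A1 == eQTL A2) -> GWAS beta sign is flipped
      and ``flipped=True``;
    * opposite-strand codings are resolved by complementing;
    * incompatible alleles -> dropped (reason ``allele_mismatch``);
    * strand-ambiguous SNPs (A/T, C/G) -> dropped iff ``drop_ambiguous``
      (reason ``strand_ambiguous``).

    Exclusion reasons are tallied in the returned list's ``.exclusions``.
    """
    gwas_by_snp = {r.snp_id: r for r in gwas}
    out: list[HarmonizedPair] = []
    exclusions: Counter = Counter()
    for e in eqtl:
        g = gwas_by_snp.get(e.snp_id)
        if g is None:
            exclusions["not_in_gwas"] += 1
            continue
        if is_strand_ambiguous(e.effect_allele, e.other_allele) or \
                is_strand_ambiguous(g.effect_allele, g.other_allele):
            if drop_ambiguous:
                exclusions["strand_ambiguous"] += 1
                continue
        ga1, ga2 = g.effect_allele, g.other_allele
        ca1 = _COMPLEMENT.get(ga1, ga1)
        ca2 = _COMPLEMENT.get(ga2, ga2)
        if (ga1, ga2) == (e.effect_allele, e.other_allele) or \
                (ca1, ca2) == (e.effect_allele, e.other_allele):
            beta_zy, flipped = g.beta_zy, False
        elif (ga2, ga1) == (e.effect_allele, e.other_allele) or \
                (ca2, ca1) == (e.effect_allele, e.other_allele):
            beta_zy, flipped = -g.beta_zy, True
        else:
            exclusions["allele_mismatch"] += 1
            continue
        out.append(HarmonizedPair(
            snp_id=e.snp_id, gene_id=e.gene_id, beta_zy=beta_zy,
            se_zy=g.se_zy, n_gwas=g.n, beta_zx=e.beta_zx, se_zx=e.se_zx,
            p_zx=e.p_zx, flipped=flipped, pos=g.pos))
    if exclusions:
        logger.info("harmonize: exclusions %s", dict(exclusions))
    return RecordList(out, exclusions=exclusions)
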