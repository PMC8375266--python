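"""End-to-end orchestration: simulate -> encode -> train/CV -> predict ->
SMR -> overlap, with a reproducibility manifest.

A single global seed fans out into independent per-stage seeds through a
``numpy.random.SeedSequence`` spawn, so re-running an identical config
reproduces byte-identical outputs while the stages stay statistically
independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (build_labeled_features, cross_validate_resampled,
                         compare_baselines, fit_final_model, predict_novel,
                         sample_negatives)
from .io_summary import read_edge_list, read_eqtl, read_gene_list, read_gwas
from .rw_encoder import EmbeddingMatrix, GeneNetwork, RwConfig, encode_network, rwr_encode
from .smr import SmrConfig, overlap_genes, run_smr, smr_table
from .synthetic_data import SimulationConfig, simulate_all, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "report"]

STAGES = ("synthetic_data", "io_summary", "rw_encoder", "classifier",
          "smr", "overlap")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Everything a reproducible run needs; loadable from YAML."""

    outdir: str = "smrwalk_run"
    seed: int = 0
    simulate: bool = True
    # used only when simulate=False
    gwas_path: str | None = None
    gwas_dialect: str = "ma"
    eqtl_path: str | None = None
    network_path: str | None = None
    seed_genes_path: str | None = None
    encoder: str = "rw"  # "rw" or "rwr"
    restart_prob: float = 0.3
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "auto"
    cv_k: int = 10
    n_negative_resamplings: int = 10
    threshold: float = 0.0
    run_baselines: bool = False
    log_level: str = "INFO"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    rw: RwConfig = field(default_factory=RwConfig)
    smr: SmrConfig = field(default_factory=SmrConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("sim", SimulationConfig), ("rw", RwConfig),
                         ("smr", SmrConfig)):
            if key in raw and isinstance(raw[key], dict):
                if key == "sim" and "maf_range" in raw[key]:
                    raw[key]["maf_range"] = tuple(raw[key]["maf_range"])
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage sub-seeds below 2**31."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {s: int(c.generate_state(1)[0] % (2**31))
                for s, c in zip(STAGES, children)}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline, writing every artifact under
    ``cfg.outdir`` and returning the manifest (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _rel(p) -> str:
        # manifests carry outdir-relative paths so identical configs give
        # byte-identical manifests regardless of where the run lives
        return str(Path(p).relative_to(outdir))

    seeds = cfg.stage_seeds()
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stage_seeds": seeds, "artifacts": {}, "counts": {},
                      "inputs": {}}

    stage = "synthetic_data"
    try:
        if cfg.simulate:
            sim_cfg = dataclasses.replace(cfg.sim, seed=seeds[stage])
            gwas, eqtl, net, truth = simulate_all(sim_cfg)
            paths = write_dataset(outdir / "inputs", gwas, eqtl, net, truth)
            manifest["artifacts"].update({k: _rel(v) for k, v in paths.items()})
            seed_genes = sorted(net.seed_genes)
        else:
            stage = "io_summary"
            gwas = read_gwas(cfg.gwas_path, dialect=cfg.gwas_dialect)
            eqtl = read_eqtl(cfg.eqtl_path)
            seed_genes = read_gene_list(cfg.seed_genes_path)
            net = GeneNetwork.from_edges(read_edge_list(cfg.network_path),
                                         seed_genes=seed_genes)
            manifest["inputs"] = {
                "gwas": _sha256(cfg.gwas_path),
                "eqtl": _sha256(cfg.eqtl_path),
                "network": _sha256(cfg.network_path),
                "seed_genes": _sha256(cfg.seed_genes_path)}
        manifest["counts"]["gwas_records"] = len(gwas)
        manifest["counts"]["eqtl_records"] = len(eqtl)
        manifest["counts"]["network_nodes"] = net.n_nodes
        manifest["counts"]["network_edges"] = net.graph.number_of_edges()
        manifest["counts"]["seed_genes"] = len(seed_genes)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - error routing names the stage
        raise StageError(stage, exc) from exc

    stage = "rw_encoder"
    try:
        if cfg.encoder == "rw":
            rw_cfg = dataclasses.replace(cfg.rw, seed=seeds[stage])
            emb = encode_network(net, rw_cfg)
        elif cfg.encoder == "rwr":
            emb = rwr_encode(net, restart_prob=cfg.restart_prob)
        else:
            raise ValueError(f"unknown encoder {cfg.encoder!r}")
        emb_path = outdir / "embedding.tsv"
        emb.to_frame().to_csv(emb_path, sep="\t")
        manifest["artifacts"]["embedding"] = _rel(emb_path)
        manifest["counts"]["embedding_dim"] = emb.dim
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "classifier"
    try:
        svm_kwargs = dict(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
        report_cv = cross_validate_resampled(
            emb, net, k=cfg.cv_k, n_resamplings=cfg.n_negative_resamplings,
            seed=seeds[stage], **svm_kwargs)
        cv_path = outdir / "cv_report.tsv"
        pd.DataFrame({
            "resampling": range(len(report_cv.fold_auc)),
            "auc": report_cv.fold_auc,
            "aupr": report_cv.fold_aupr}).to_csv(cv_path, sep="\t", index=False)
        manifest["artifacts"]["cv_report"] = _rel(cv_path)
        manifest["counts"]["cv_mean_auc"] = round(report_cv.mean_auc, 6)
        manifest["counts"]["cv_mean_aupr"] = round(report_cv.mean_aupr, 6)
        if cfg.run_baselines:
            negatives = sample_negatives(net, len(seed_genes),
                                         seed=seeds[stage])
            data_b = build_labeled_features(emb, seed_genes, sorted(negatives))
            bl = compare_baselines(data_b, k=cfg.cv_k, seed=seeds[stage])
            bl_path = outdir / "baselines.tsv"
            bl.to_csv(bl_path, sep="\t", index=False)
            manifest["artifacts"]["baselines"] = _rel(bl_path)
        negatives = sample_negatives(net, len(seed_genes), seed=seeds[stage])
        data = build_labeled_features(emb, seed_genes, sorted(negatives))
        model, scaler = fit_final_model(data, **svm_kwargs)
        preds = predict_novel(model, scaler, data.unlabeled_ids,
                              data.X_unlabeled, threshold=cfg.threshold)
        pred_path = outdir / "predictions.tsv"
        pred_df = pd.DataFrame(sorted(preds.scores.items()),
                               columns=["gene", "score"])
        pred_df["predicted"] = [int(g in preds.predicted_positive)
                                for g in pred_df["gene"]]
        pred_df.to_csv(pred_path, sep="\t", index=False)
        manifest["artifacts"]["predictions"] = _rel(pred_path)
        manifest["counts"]["predicted_genes"] = len(preds.predicted_positive)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "smr"
    try:
        results = run_smr(gwas, eqtl, cfg.smr)
        smr_path = outdir / "smr.tsv"
        smr_table(results).to_csv(smr_path, sep="\t", index=False)
        manifest["artifacts"]["smr"] = _rel(smr_path)
        manifest["counts"].update(results.counts)
        sig = results.significant_genes()
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "overlap"
    try:
        inter, jaccard = overlap_genes(sig, preds.predicted_positive)
        ov_path = outdir / "overlap.json"
        ov = {"smr_significant": sorted(sig),
              "svm_predicted": sorted(preds.predicted_positive),
              "overlap": sorted(inter), "jaccard": round(jaccard, 6)}
        ov_path.write_text(json.dumps(ov, indent=2, sort_keys=True) + "\n")
        manifest["artifacts"]["overlap"] = _rel(ov_path)
        manifest["counts"]["overlap_genes"] = len(inter)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable accounting of every filter step, from the manifest.

    Missing entries are reported as gaps, never silently dropped.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    counts = manifest.get("counts", {})
    order = ["gwas_records", "eqtl_records", "network_nodes", "network_edges",
             "seed_genes", "embedding_dim", "cv_mean_auc", "cv_mean_aupr",
             "gwas_snps", "eqtl_pairs", "shared_snps", "harmonized_pairs",
             "genes_tested", "significant_genes", "predicted_genes",
             "overlap_genes"]
    lines = [f"smrwalk {manifest.get('version', '?')} run "
             f"(seed {manifest.get('seed', '?')})"]
    for key in order:
        val = counts.get(key, "<missing>")
        lines.append(f"  {key:<20} {val}")
    extras = sorted(set(counts) - set(order))
    for key in extras:
        lines.append(f"  {key:<20} {counts[key]}")
    return "\n".join(lines)
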