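"""End-to-end orchestration: simulate -> respond -> GSEA -> enrich -> MR.

Every stage writes plain TSV/JSON into the output directory so each can be
re-run standalone; the final report collects gene counts at every filter,
pi1 summaries, enrichment statistics and the MR results.  Runs are
idempotent given the seed (the report carries a timestamp field only).
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, mr
from .enrichment import (compare_proportions, esnps_for_genes, gwas_enrichment,
                         permutation_enrichment)
from .errors import ConfigError, DataError
from .gsea import gsea_preranked, rank_genes
from .pi1 import estimate_pi0
from .response import (compute_response, filter_detected_genes,
                       test_differential_response, test_response_all)
from .simulate import (SimulationConfig, TruthTable, make_gene_sets,
                       simulate_expression_study, simulate_reference_panel,
                       simulate_summary_statistics)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    response_p: float = 0.01
    eqtl_fdr: float = 0.05
    gwas_alpha: float = 0.05
    r2_prune: float = 0.2
    r2_proxy: float = 0.8
    n_permutations: int = 1000
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    detection_alpha: float = 0.01
    detection_min_fraction: float = 0.0

    def __post_init__(self):
        for name in ("response_p", "eqtl_fdr", "gwas_alpha", "r2_prune",
                     "r2_proxy", "detection_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"threshold {name}={v} outside (0, 1)")
        if self.n_permutations < 100 or self.gsea_n_perm < 100:
            raise ConfigError("permutation counts must be >= 100")


@dataclass
class RunConfig:
    """Either a simulation block or paths to pre-existing input tables."""

    out_dir: str
    seed: int = 0
    simulation: dict | None = None
    paths: dict = field(default_factory=dict)   # expression/eqtl/gwas/panel/gene_sets
    thresholds: Thresholds = field(default_factory=Thresholds)
    diff_group_a: str = "PDR"
    diff_group_b: str = "nDR"
    mr_gene: str | None = None

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        slots = ("expression", "eqtl", "gwas", "panel")
        if self.simulation is None and not all(s in self.paths for s in slots):
            raise ConfigError(
                "provide either a simulation block or paths for "
                f"{slots}")
        if self.simulation is not None:
            clash = [s for s in slots if s in self.paths]
            if clash:
                raise ConfigError(
                    f"simulation block and input paths both given for {clash}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except (ConfigError, DataError):
                raise
            except Exception as exc:            # annotate unexpected failures
                raise DataError(
                    f"stage {name!r} failed: {exc}; check the stage inputs "
                    "in the output directory") from exc
        return wrapper
    return deco


@_stage("simulate")
def _acquire_inputs(config: RunConfig, out: Path):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        panel = simulate_reference_panel(sim)
        expr, truth = simulate_expression_study(sim, panel)
        eqtl, gwas = simulate_summary_statistics(sim, panel, truth)
        gene_sets = make_gene_sets(sim, truth)
        io.write_expression_tsv(expr, out / "expression.tsv")
        io.write_eqtl_tsv(eqtl, out / "eqtl.tsv")
        io.write_gwas_tsv(gwas, out / "gwas.tsv")
        io.write_dosage_tsv(panel, out / "panel.tsv")
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
        truth.to_json(out / "truth.json")
        return expr, eqtl, gwas, panel, gene_sets, truth
    expr = io.read_expression_tsv(config.paths["expression"])
    eqtl = io.read_eqtl_tsv(config.paths["eqtl"])
    gwas = io.read_gwas_tsv(config.paths["gwas"])
    panel_path = str(config.paths["panel"])
    panel = (io.read_vcf(panel_path) if panel_path.endswith(".vcf")
             else io.read_dosage_tsv(panel_path))
    gene_sets = (io.read_gmt(config.paths["gene_sets"])
                 if "gene_sets" in config.paths else None)
    truth = (TruthTable.from_json(config.paths["truth"])
             if "truth" in config.paths else None)
    return expr, eqtl, gwas, panel, gene_sets, truth


@_stage("respond")
def _respond(config: RunConfig, expr, out: Path):
    thr = config.thresholds
    expr = filter_detected_genes(expr, alpha=thr.detection_alpha,
                                 min_fraction=thr.detection_min_fraction)
    resp = compute_response(expr)
    all_res = test_response_all(resp)
    diff_res = test_differential_response(resp, config.diff_group_a,
                                          config.diff_group_b)
    for name, frame in (("response_all", all_res), ("response_diff", diff_res)):
        (frame.rename_axis("gene_id")
         .to_csv(out / f"{name}.tsv", sep="\t", float_format="%.6g"))
    top = diff_res[diff_res["pvalue"] < thr.response_p].index
    (out / "top_diff_genes.txt").write_text("\n".join(top) + "\n")
    return resp, all_res, diff_res, list(top)


@_stage("gsea")
def _gsea(config: RunConfig, all_res, gene_sets, out: Path):
    if not gene_sets:
        log.warning("no gene sets supplied; GSEA skipped")
        return None
    thr = config.thresholds
    ranked = rank_genes(all_res)
    try:
        res = gsea_preranked(ranked, gene_sets, n_perm=thr.gsea_n_perm,
                             min_size=thr.gsea_min_size,
                             max_size=thr.gsea_max_size, seed=config.seed)
    except DataError as exc:
        log.warning("GSEA skipped: %s", exc)
        return None
    res.to_csv(out / "gsea.tsv", sep="\t", float_format="%.6g")
    return res


@_stage("enrich")
def _enrich(config: RunConfig, top_genes, eqtl, gwas, all_res, out: Path):
    thr = config.thresholds
    esnps = esnps_for_genes(eqtl, top_genes, fdr_max=thr.eqtl_fdr)
    result: dict = {"n_top_genes": len(top_genes), "n_esnps": len(esnps)}
    if not esnps:
        log.warning("no eSNPs for the top genes; enrichment stage reduced")
        return result
    summary = gwas_enrichment(esnps, gwas, alpha=thr.gwas_alpha)
    summary.qq_points.to_csv(out / "qq_points.tsv", sep="\t", index=False,
                             float_format="%.6g")
    perm_p = permutation_enrichment(
        summary.proportion_small_p, len(top_genes), eqtl, gwas,
        B=thr.n_permutations, statistic="proportion_small_p",
        alpha=thr.gwas_alpha, fdr_max=thr.eqtl_fdr, seed=config.seed)
    summary.permutation_p = perm_p
    summary.permutation_statistic = "proportion_small_p"

    all_esnps = esnps_for_genes(eqtl, eqtl["gene_id"].unique(),
                                fdr_max=thr.eqtl_fdr)
    snp_ids = gwas["snp_id"].astype(str).str.lower()
    sub_p = gwas.loc[snp_ids.isin({s.lower() for s in esnps}), "pvalue"]
    esnp_p = gwas.loc[snp_ids.isin({s.lower() for s in all_esnps}), "pvalue"]
    result.update(summary.to_dict())
    result["p_vs_all_esnps"] = compare_proportions(sub_p, esnp_p,
                                                   alpha=thr.gwas_alpha)
    result["p_vs_all_snps"] = compare_proportions(sub_p, gwas["pvalue"],
                                                  alpha=thr.gwas_alpha)
    result["pi1_response_all"] = estimate_pi0(all_res["pvalue"]).pi1
    result["pi1_esnp_gwas"] = estimate_pi0(sub_p.to_numpy()).pi1
    io.write_json(result, out / "enrichment.json")
    return result


@_stage("mr")
def _mendelian(config: RunConfig, eqtl, gwas, panel, truth, out: Path):
    thr = config.thresholds
    gene = config.mr_gene
    if gene is None and truth is not None and truth.mediated_genes:
        gene = truth.mediated_genes[0]
    if gene is None:
        log.warning("no MR target gene (set mr_gene); MR stage skipped")
        return None
    rows = eqtl[(eqtl["gene_id"] == gene) & (eqtl["fdr"] <= thr.eqtl_fdr)]
    if rows.empty:
        log.warning("gene %s has no significant eSNPs; MR skipped", gene)
        report = {"gene": gene, "note": "no significant instruments"}
        io.write_json(report, out / "mr.json")
        return report
    instruments = mr.harmonize(rows, gwas)
    in_panel = instruments["snp_id"].isin(panel.snp_ids)
    instruments = instruments[in_panel].reset_index(drop=True)
    if instruments.empty:
        report = {"gene": gene, "note": "instruments absent from panel"}
        io.write_json(report, out / "mr.json")
        return report
    ld = mr.compute_ld(panel, list(instruments["snp_id"]))
    instruments = instruments[
        instruments["snp_id"].isin(ld.snp_ids)].reset_index(drop=True)
    top = instruments.sort_values(["p_zx", "snp_id"]).iloc[0]
    result = mr.smr_test(top)
    t_h, p_h, n_h = mr.heidi_test(instruments, ld)
    result.heidi_p, result.heidi_n = p_h, n_h
    pruned = mr.prune_ld(instruments, ld, r2_max=thr.r2_prune)
    _, p_multi = mr.multi_snp_smr(pruned, ld, r2_max=thr.r2_prune)
    result.multi_p = p_multi
    result.n_instruments = len(pruned)
    report = result.to_dict()
    report["gene"] = gene
    report["pruned_ids"] = list(pruned["snp_id"])
    instruments.to_csv(out / "mr_instruments.tsv", sep="\t", index=False,
                       float_format="%.6g")
    io.write_json(report, out / "mr.json")
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return (and write) the top-level report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, eqtl, gwas, panel, gene_sets, truth = _acquire_inputs(config, out)
    resp, all_res, diff_res, top_genes = _respond(config, expr, out)
    gsea_res = _gsea(config, all_res, gene_sets, out)
    enrich_res = _enrich(config, top_genes, eqtl, gwas, all_res, out)
    mr_res = _mendelian(config, eqtl, gwas, panel, truth, out)

    from . import __version__
    report = {
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_genes_input": int(expr.values.shape[0]),
        "n_individuals": int(resp.delta.shape[1]),
        "n_genes_tested": int(all_res.shape[0]),
        "n_response_fdr05": int((all_res["qvalue"] < 0.05).sum()),
        "n_diff_response_p01": len(top_genes),
        "top_response_gene": str(all_res["pvalue"].idxmin()),
        "gsea_n_sets": None if gsea_res is None else int(gsea_res.shape[0]),
        "enrichment": enrich_res,
        "mr": mr_res,
    }
    io.write_json(report, out / "report.json")
    return report
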