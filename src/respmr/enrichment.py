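"""eSNP collection, eGene over-representation and GWAS p-value enrichment.

Links a gene list (typically the differential-response genes) to its
significant eSNPs, summarizes their GWAS p-values (proportion below alpha,
BH within the set, Bonferroni threshold, genomic-control lambda, QQ points)
and calibrates the observed enrichment against eSNP sets of random eGene
draws of the same size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, two_proportion_z
from .errors import ConfigError, DataError

__all__ = [
    "EnrichmentSummary",
    "esnps_for_genes",
    "egene_enrichment",
    "gwas_enrichment",
    "permutation_enrichment",
    "compare_proportions",
]

log = logging.getLogger(__name__)

# median of chi-square(1): exact null expectation for lambda_GC
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class EnrichmentSummary:
    n_esnps: int
    proportion_small_p: float
    bh_min_q: float
    bh_hits: int
    bonferroni_threshold: float
    bonferroni_hits: int
    lambda_gc: float
    alpha: float
    n_missing: int = 0
    permutation_p: float | None = None
    permutation_statistic: str | None = None
    qq_points: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("qq_points")
        return d


def _normalize_ids(ids) -> pd.Series:
    return pd.Series(list(ids), dtype=str).str.lower()


def esnps_for_genes(eqtl: pd.DataFrame, genes, fdr_max: float = 0.05) -> set:
    """Unique SNPs with fdr <= fdr_max for any listed gene in any tissue."""
    genes = set(genes)
    if not genes:
        raise DataError("gene list is empty")
    hit = eqtl[(eqtl["gene_id"].isin(genes)) & (eqtl["fdr"] <= fdr_max)]
    snps = set(hit["snp_id"].astype(str))
    if not snps:
        log.info("no significant eSNPs found for %d genes", len(genes))
    return snps


def egene_enrichment(genes, universe_genes, egene_set) -> tuple[float, float, float]:
    """Two-proportion z-test of eGene fraction in `genes` vs the universe."""
    genes, universe, egenes = set(genes), set(universe_genes), set(egene_set)
    if not genes or not universe:
        raise DataError("empty gene sets")
    if not genes <= universe:
        raise DataError("genes must be a subset of the universe")
    k_a = len(genes & egenes)
    k_b = len(universe & egenes)
    _, p = two_proportion_z(k_a, len(genes), k_b, len(universe),
                            alternative="two-sided")
    return k_a / len(genes), k_b / len(universe), p


def gwas_enrichment(esnps, gwas: pd.DataFrame, alpha: float = 0.05
                    ) -> EnrichmentSummary:
    """GWAS p-value summary of an eSNP set.

    lambda_GC is the median association chi-square over its null median;
    SNP ids are matched case-insensitively; eSNPs absent from the GWAS are
    logged and skipped.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    esnps = set(_normalize_ids(esnps))
    if not esnps:
        raise DataError("empty eSNP set")
    gwas_ids = _normalize_ids(gwas["snp_id"])
    mask = gwas_ids.isin(esnps).to_numpy()
    found = set(gwas_ids[mask])
    missing = esnps - found
    if not found:
        examples = sorted(missing)[:5]
        raise DataError(f"no eSNP found in GWAS; unmatched examples: {examples}")
    if missing:
        log.warning("%d eSNPs missing from GWAS (e.g. %s)", len(missing),
                    sorted(missing)[:3])
    p = gwas.loc[mask, "pvalue"].to_numpy(dtype=float)
    n = p.size
    q = bh_qvalues(p)
    bonf = alpha / n
    chi2 = stats.chi2.ppf(1.0 - p, df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    order = np.sort(p)
    qq = pd.DataFrame({
        "expected_neglog10": -np.log10((np.arange(1, n + 1) - 0.5) / n),
        "observed_neglog10": -np.log10(order),
    })
    return EnrichmentSummary(
        n_esnps=n,
        proportion_small_p=float((p < alpha).mean()),
        bh_min_q=float(q.min()),
        bh_hits=int((q < alpha).sum()),
        bonferroni_threshold=bonf,
        bonferroni_hits=int((p < bonf).sum()),
        lambda_gc=lam,
        alpha=alpha,
        n_missing=len(missing),
        qq_points=qq,
    )


def _gene_snp_index(eqtl: pd.DataFrame, gwas: pd.DataFrame, fdr_max: float):
    """Precompute, per eGene, GWAS row indices of its significant eSNPs."""
    gwas_ids = _normalize_ids(gwas["snp_id"])
    snp_pos = pd.Series(np.arange(len(gwas_ids)), index=gwas_ids.to_numpy())
    snp_pos = snp_pos[~snp_pos.index.duplicated()]
    sig = eqtl[eqtl["fdr"] <= fdr_max]
    gene_to_idx = {}
    for gene, sub in sig.groupby("gene_id"):
        ids = _normalize_ids(sub["snp_id"].unique())
        ids = ids[ids.isin(snp_pos.index)]
        if len(ids):
            gene_to_idx[gene] = snp_pos.loc[ids].to_numpy()
    return gene_to_idx, gwas["pvalue"].to_numpy(dtype=float)


def permutation_enrichment(observed_stat: float, k_genes: int, eqtl: pd.DataFrame,
                           gwas: pd.DataFrame, B: int = 10000,
                           statistic: str = "proportion_small_p",
                           alpha: float = 0.05, fdr_max: float = 0.05,
                           seed: int = 0) -> float:
    """Empirical enrichment p from random same-size eGene draws.

    For each of B draws, sample ``k_genes`` eGenes without replacement,
    pool the GWAS p-values of their eSNPs, and compute either the
    proportion below ``alpha`` ("proportion_small_p") or the number of BH
    q < alpha hits ("bh_hits"); p = (1 + #{perm >= observed}) / (1 + B).
    """
    if B < 100:
        raise ConfigError("B must be >= 100")
    if statistic not in ("proportion_small_p", "bh_hits"):
        raise ConfigError("statistic must be 'proportion_small_p' or 'bh_hits'")
    gene_to_idx, gwas_p = _gene_snp_index(eqtl, gwas, fdr_max)
    universe = sorted(gene_to_idx)
    if len(universe) < k_genes:
        raise DataError(
            f"eGene universe ({len(universe)}) smaller than k_genes ({k_genes})")
    rng = np.random.default_rng(seed)
    arrs = [gene_to_idx[g] for g in universe]
    n_ge = 0
    for _ in range(B):
        pick = rng.choice(len(universe), size=k_genes, replace=False)
        # a SNP shared by two sampled genes is counted once, as observed
        idx = np.unique(np.concatenate([arrs[i] for i in pick]))
        pooled = gwas_p[idx]
        if statistic == "proportion_small_p":
            stat = (pooled < alpha).mean()
        else:
            stat = float((bh_qvalues(pooled) < alpha).sum())
        if stat >= observed_stat:
            n_ge += 1
    return (1.0 + n_ge) / (1.0 + B)


def compare_proportions(set_a_pvalues, set_b_pvalues, alpha: float = 0.05) -> float:
    """One-sided test that fraction{p < alpha} in A exceeds that in B."""
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    pa = np.asarray(set_a_pvalues, dtype=float)
    pb = np.asarray(set_b_pvalues, dtype=float)
    if pa.size == 0 or pb.size == 0:
        raise DataError("both p-value sets must be nonempty")
    _, p = two_proportion_z(int((pa < alpha).sum()), pa.size,
                            int((pb < alpha).sum()), pb.size,
                            alternative="greater")
    return p
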