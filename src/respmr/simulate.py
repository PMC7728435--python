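"""Synthetic genotypes, paired-condition expression and summary statistics.

The generator emulates a 22-individual study design (7 non-diabetic, 7
diabetic without retinopathy, 8 with proliferative retinopathy; three
replicates per individual in each of two glucose conditions) and a disease
model in which risk is mediated through the expression of designated genes,
so that every downstream stage (response testing, enrichment, Mendelian
randomization) can be validated against known truth.

Model
-----
Genotypes: each haplotype is an AR(1) latent Gaussian thresholded at the
per-SNP allele frequency; two haplotypes sum to a dosage in {0, 1, 2}, which
gives tunable adjacent-SNP LD.

Expression (log2 units) for gene g, individual i, replicate r, condition c:

    x = baseline_g + a_i + beta_g * dosage_i
        + (resp_g + u_{g,i} + diff_g * 1[i in PDR]) * 1[c == HG] + eps

with ``a_i`` a per-individual offset (cancels in the HG-SG response),
``u_{g,i} ~ N(0, noise_sd_individual)`` an individual-specific response
deviation, and ``eps ~ N(0, noise_sd_replicate)``.

Disease: liability = b_xy * (standardized genetic expression of mediated
genes) + pleiotropy * dosage + N(0, 1); cases/controls by liability
threshold at the configured prevalence.

Cohorts (eQTL and GWAS) are drawn by resampling reference-panel rows with
replacement, so their LD matches the panel by construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, stage_rng
from .errors import ConfigError, SimulationError
from .response import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GenotypePanel",
    "TruthTable",
    "simulate_reference_panel",
    "simulate_expression_study",
    "simulate_summary_statistics",
    "simulate_locus_stats",
    "make_gene_sets",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

GROUPS = ("nDM", "nDR", "PDR")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults emulate the target design."""

    n_individuals_per_group: dict = field(
        default_factory=lambda: {"nDM": 7, "nDR": 7, "PDR": 8})
    n_replicates: int = 3
    n_genes: int = 1000
    n_snps: int = 2000
    n_response_genes: int = 220
    n_diff_response_genes: int = 103
    response_effect: float = 0.2
    response_effect_sd: float = 0.0   # >0 spreads per-gene response magnitudes
    # optional second component of stronger responders (heavy-tailed effects)
    n_strong_response_genes: int = 0
    strong_response_effect: float = 0.0
    strong_response_effect_sd: float = 0.0
    diff_response_effect: float = 0.27
    noise_sd_gene: float = 1.0
    noise_sd_individual: float = 0.1
    noise_sd_replicate: float = 0.15
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.8
    eqtl_effect_sd: float = 0.3
    mediation_effect: float = 0.15
    pleiotropy_effect: float = 0.0
    n_cases: int = 1000
    n_controls: int = 1000
    seed: int = 0
    # sizing / plumbing beyond the core design
    n_panel: int = 1000
    n_eqtl_samples: int = 500
    prevalence: float = 0.1
    n_mediated_genes: int = 1
    gwas_model: str = "logistic"     # or "liability" (linear, unascertained)
    batch_effect_sd: float = 0.0

    def __post_init__(self):
        counts = [self.n_replicates, self.n_genes, self.n_snps, self.n_cases,
                  self.n_controls, self.n_panel, self.n_eqtl_samples]
        counts += list(self.n_individuals_per_group.values())
        if any(int(c) <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if not (0 <= self.n_diff_response_genes <= self.n_response_genes
                <= self.n_genes):
            raise ConfigError(
                "need n_diff_response_genes <= n_response_genes <= n_genes")
        if not (0 <= self.n_strong_response_genes <= self.n_response_genes):
            raise ConfigError(
                "n_strong_response_genes must not exceed n_response_genes")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be a sub-interval of (0, 0.5]")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must be in (0, 1)")
        if self.gwas_model not in ("logistic", "liability"):
            raise ConfigError("gwas_model must be 'logistic' or 'liability'")
        if set(self.n_individuals_per_group) != set(GROUPS):
            raise ConfigError(f"groups must be exactly {GROUPS}")

    @property
    def n_study(self) -> int:
        return sum(self.n_individuals_per_group.values())

    @property
    def snps_per_gene(self) -> int:
        return self.n_snps // self.n_genes

    def gene_ids(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def snp_ids(self) -> list:
        return [f"rs{100000 + i}" for i in range(self.n_snps)]

    def gene_block(self, gene_index: int) -> slice:
        """SNP-index block assigned to a gene (empty if n_snps < n_genes)."""
        spg = self.snps_per_gene
        return slice(gene_index * spg, (gene_index + 1) * spg)


@dataclass
class GenotypePanel:
    """Reference dosage panel: individuals x SNPs in {0, 1, 2}."""

    dosages: np.ndarray
    snp_ids: list
    allele_freqs: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ConfigError("dosages must be individuals x len(snp_ids)")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ConfigError("dosages must be in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def index_of(self, snps) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snps], dtype=int)
        except KeyError as exc:
            raise ConfigError(f"SNP not in panel: {exc.args[0]!r}") from None


@dataclass
class TruthTable:
    """Ground truth of one simulated study (the acceptance oracle)."""

    response_genes: list
    diff_response_genes: list
    eqtl_map: dict                 # gene_id -> [snp_id, true beta]
    true_b_xy: float
    pleiotropic_snps: list
    mediated_genes: list = field(default_factory=list)
    response_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.diff_response_genes) - set(self.response_genes)
        if missing:
            raise ConfigError(
                f"diff-response genes must respond to glucose: {sorted(missing)[:3]}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))


def simulate_reference_panel(config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             n_individuals: int | None = None) -> GenotypePanel:
    """Dosage panel with AR(1) latent LD between adjacent SNPs."""
    rng = rng if rng is not None else stage_rng(config.seed, "panel")
    n = int(n_individuals or config.n_panel)
    m = config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    thresholds = stats.norm.ppf(freqs)  # latent < t  =>  carries the allele
    dosages = np.zeros((n, m), dtype=np.int8)
    rho = config.ld_rho
    innov_sd = np.sqrt(1.0 - rho ** 2)
    for _hap in range(2):
        latent = np.empty((n, m))
        latent[:, 0] = rng.standard_normal(n)
        noise = rng.standard_normal((n, m - 1)) * innov_sd if m > 1 else None
        for j in range(1, m):
            latent[:, j] = rho * latent[:, j - 1] + noise[:, j - 1]
        dosages += (latent < thresholds).astype(np.int8)
    return GenotypePanel(dosages=dosages, snp_ids=config.snp_ids(),
                         allele_freqs=freqs)


def _study_individuals(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for group in GROUPS:
        for _ in range(config.n_individuals_per_group[group]):
            rows.append((f"IND{i:03d}", group))
            i += 1
    return pd.DataFrame(rows, columns=["individual", "group"])


def simulate_expression_study(config: SimulationConfig, panel: GenotypePanel,
                              rng: np.random.Generator | None = None
                              ) -> tuple[ExpressionMatrix, TruthTable]:
    """Replicate-level SG/HG expression plus the generating truth."""
    rng = rng if rng is not None else stage_rng(config.seed, "expression")
    n_ind = config.n_study
    if panel.n_individuals < n_ind:
        raise ConfigError(
            f"panel has {panel.n_individuals} individuals, study needs {n_ind}")

    genes = config.gene_ids()
    n_genes = config.n_genes
    individuals = _study_individuals(config)
    is_pdr = (individuals["group"] == "PDR").to_numpy()

    # planted structure: diff-response genes are the first block of the
    # response genes so diff subset-of-response holds by construction
    response_idx = np.arange(config.n_response_genes)
    diff_idx = np.arange(config.n_diff_response_genes)

    resp_effect = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=config.n_response_genes)
    magnitudes = config.response_effect + config.response_effect_sd * \
        rng.standard_normal(config.n_response_genes)
    n_strong = config.n_strong_response_genes
    if n_strong:
        magnitudes[:n_strong] = (config.strong_response_effect
                                 + config.strong_response_effect_sd
                                 * rng.standard_normal(n_strong))
    resp_effect[response_idx] = signs * magnitudes
    # group-differential effect: PDR responds more strongly (positive shift)
    diff_effect = np.zeros(n_genes)
    diff_effect[diff_idx] = config.diff_response_effect

    baseline = 8.0 + config.noise_sd_gene * rng.standard_normal(n_genes)
    ind_offset = 0.5 * config.noise_sd_gene * rng.standard_normal(n_ind)
    resp_dev = config.noise_sd_individual * rng.standard_normal((n_genes, n_ind))

    # cis genetic effect on steady-state expression
    eqtl_map = {}
    genetic = np.zeros((n_genes, n_ind))
    spg = config.snps_per_gene
    if spg >= 1:
        causal = np.arange(n_genes) * spg + spg // 2
        betas = config.eqtl_effect_sd * rng.standard_normal(n_genes)
        genetic = betas[:, None] * panel.dosages[:n_ind, causal].T
        for g in range(n_genes):
            eqtl_map[genes[g]] = [panel.snp_ids[causal[g]], float(betas[g])]

    batch_offsets = config.batch_effect_sd * rng.standard_normal(config.n_replicates)

    columns, data = [], []
    for cond_flag, cond in ((0, "SG"), (1, "HG")):
        hg_term = (resp_effect[:, None] + resp_dev
                   + np.where(is_pdr, diff_effect[:, None], 0.0)) if cond_flag else 0.0
        base = baseline[:, None] + ind_offset[None, :] + genetic + hg_term
        for rep in range(1, config.n_replicates + 1):
            eps = config.noise_sd_replicate * rng.standard_normal((n_genes, n_ind))
            block = base + eps + batch_offsets[rep - 1]
            for j, ind in enumerate(individuals["individual"]):
                columns.append(f"{ind}_{cond}_r{rep}")
                data.append(block[:, j])
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)

    sample_meta = []
    for col in columns:
        ind, cond, rep = col.rsplit("_", 2)
        group = individuals.set_index("individual")["group"][ind]
        sample_meta.append((col, ind, int(rep[1:]), cond, group))
    samples = pd.DataFrame(
        sample_meta, columns=["sample", "individual", "replicate",
                              "condition", "group"]).set_index("sample")

    # mediated genes: the diff-response genes with the strongest cis effects
    # (the disease-gene analogue should have usable instruments)
    diff_with_eqtl = [g for g in diff_idx if genes[g] in eqtl_map]
    diff_with_eqtl.sort(key=lambda g: -abs(eqtl_map[genes[g]][1]))
    mediated = [genes[g] for g in diff_with_eqtl[:config.n_mediated_genes]]
    pleio = []
    if config.pleiotropy_effect != 0.0 and spg >= 3:
        for g in diff_idx[:config.n_mediated_genes]:
            blk = config.gene_block(g)
            pleio.append(panel.snp_ids[min(blk.start + spg // 2 + 2, blk.stop - 1)])

    truth = TruthTable(
        response_genes=[genes[g] for g in response_idx],
        diff_response_genes=[genes[g] for g in diff_idx],
        eqtl_map=eqtl_map,
        true_b_xy=config.mediation_effect,
        pleiotropic_snps=pleio,
        mediated_genes=mediated,
        response_effects={genes[g]: float(resp_effect[g]) for g in response_idx},
    )
    expr = ExpressionMatrix(values=values, samples=samples)
    return expr, truth


# --------------------------------------------------------------------------
# summary statistics


def _linear_assoc(y: np.ndarray, dosages: np.ndarray):
    """Vectorized per-column simple OLS of y on dosage; (beta, se, p)."""
    n = y.shape[0]
    g = dosages.astype(float)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    sxx = np.where(sxx <= 0, np.nan, sxx)
    beta = gc.T @ yc / sxx
    resid_ss = (yc ** 2).sum() - beta ** 2 * sxx
    sigma2 = np.maximum(resid_ss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _logistic_assoc(y: np.ndarray, dosages: np.ndarray, chunk: int = 256,
                    max_iter: int = 30, tol: float = 1e-8):
    """Per-SNP two-parameter logistic regression via chunked Newton steps."""
    n, m = dosages.shape
    beta = np.zeros(m)
    se = np.zeros(m)
    y = y.astype(float)
    for start in range(0, m, chunk):
        g = dosages[:, start:start + chunk].astype(float)
        k = g.shape[1]
        a = np.full(k, np.log(y.mean() / (1 - y.mean())))
        b = np.zeros(k)
        for _ in range(max_iter):
            eta = a[None, :] + g * b[None, :]
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            r = y[:, None] - p
            g0 = r.sum(axis=0)
            g1 = (r * g).sum(axis=0)
            h00 = w.sum(axis=0)
            h01 = (w * g).sum(axis=0)
            h11 = (w * g * g).sum(axis=0)
            det = h00 * h11 - h01 ** 2
            det = np.where(det <= 0, np.nan, det)
            da = (h11 * g0 - h01 * g1) / det
            db = (h00 * g1 - h01 * g0) / det
            a = a + da
            b = b + db
            if np.nanmax(np.abs(np.concatenate([da, db]))) < tol:
                break
        eta = a[None, :] + g * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g * g).sum(axis=0)
        det = h00 * h11 - h01 ** 2
        det = np.where(det <= 0, np.nan, det)
        beta[start:start + chunk] = b
        se[start:start + chunk] = np.sqrt(h00 / det)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _resample(panel: GenotypePanel, n: int, rng) -> np.ndarray:
    return panel.dosages[rng.integers(0, panel.n_individuals, size=n)]


def _alleles(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_snps)
    eff = np.array([_ALLELE_PAIRS[i][0] for i in idx])
    oth = np.array([_ALLELE_PAIRS[i][1] for i in idx])
    return eff, oth


def _liability(config: SimulationConfig, truth: TruthTable, dosages: np.ndarray,
               panel: GenotypePanel, rng) -> np.ndarray:
    """Liability = mediated genetic expression (SD units) + pleiotropy + noise."""
    n = dosages.shape[0]
    liab = np.zeros(n)
    mediated = truth.mediated_genes
    if mediated and truth.true_b_xy != 0.0:
        scale = np.sqrt(len(mediated))
        for gene in mediated:
            snp, beta = truth.eqtl_map[gene]
            j = panel.snp_ids.index(snp)
            f = panel.allele_freqs[j]
            sd_x = np.sqrt(beta ** 2 * 2 * f * (1 - f) + 1.0)
            liab += truth.true_b_xy * beta * dosages[:, j] / sd_x / scale
    if truth.pleiotropic_snps and config.pleiotropy_effect != 0.0:
        cols = panel.index_of(truth.pleiotropic_snps)
        liab += config.pleiotropy_effect * dosages[:, cols].sum(axis=1)
    return liab + rng.standard_normal(n)


def simulate_summary_statistics(config: SimulationConfig, panel: GenotypePanel,
                                truth: TruthTable,
                                rng: np.random.Generator | None = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """eQTL and GWAS summary tables under the mediation disease model.

    eQTL rows: per-(gene, block SNP) simple regression of standardized
    steady-state expression on dosage in a resampled cohort.  GWAS rows:
    per-SNP association of disease with dosage (logistic on threshold-sampled
    cases/controls, or linear on the continuous liability when
    ``config.gwas_model == "liability"``).
    """
    if not truth.eqtl_map:
        raise ConfigError("truth.eqtl_map is empty; nothing to simulate")
    rng = rng if rng is not None else stage_rng(config.seed, "summary")
    eff_alleles, oth_alleles = _alleles(config, rng)
    genes = config.gene_ids()

    # ---- eQTL table
    geno = _resample(panel, config.n_eqtl_samples, rng)
    rows = []
    for g, gene in enumerate(genes):
        if gene not in truth.eqtl_map:
            continue
        blk = config.gene_block(g)
        snp, beta = truth.eqtl_map[gene]
        causal = panel.snp_ids.index(snp)
        x = beta * geno[:, causal] + rng.standard_normal(geno.shape[0])
        sd = x.std(ddof=1)
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        b, se, p = _linear_assoc(x, geno[:, blk])
        for j, snp_idx in enumerate(range(blk.start, blk.stop)):
            rows.append((gene, panel.snp_ids[snp_idx], "SIM", b[j], se[j], p[j],
                         eff_alleles[snp_idx], oth_alleles[snp_idx]))
    eqtl = pd.DataFrame(rows, columns=["gene_id", "snp_id", "tissue", "beta",
                                       "se", "pvalue", "effect_allele",
                                       "other_allele"])
    eqtl["fdr"] = bh_qvalues(eqtl["pvalue"].to_numpy())
    eqtl = eqtl[["gene_id", "snp_id", "tissue", "beta", "se", "pvalue", "fdr",
                 "effect_allele", "other_allele"]]

    # ---- GWAS table
    if config.gwas_model == "liability":
        cohort = _resample(panel, config.n_cases + config.n_controls, rng)
        y = _liability(config, truth, cohort, panel, rng)
        b, se, p = _linear_assoc(y, cohort)
    else:
        n_pop = int(np.ceil(max(config.n_cases / config.prevalence,
                                config.n_controls / (1 - config.prevalence)) * 1.25))
        pop = _resample(panel, n_pop, rng)
        liab = _liability(config, truth, pop, panel, rng)
        thr = np.quantile(liab, 1.0 - config.prevalence)
        case_idx = np.flatnonzero(liab > thr)
        ctrl_idx = np.flatnonzero(liab <= thr)
        if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
            raise SimulationError(
                "not enough cases/controls sampled; raise n_panel or prevalence")
        keep = np.concatenate([
            rng.choice(case_idx, size=config.n_cases, replace=False),
            rng.choice(ctrl_idx, size=config.n_controls, replace=False)])
        y = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
        b, se, p = _logistic_assoc(y, pop[keep])

    gwas = pd.DataFrame({
        "snp_id": panel.snp_ids,
        "chrom": "1",
        "pos_1based": 1 + 5000 * np.arange(config.n_snps),
        "effect_allele": eff_alleles,
        "other_allele": oth_alleles,
        "beta": b,
        "se": se,
        "pvalue": p,
    })
    return eqtl, gwas


def simulate_locus_stats(panel: GenotypePanel, snp_indices, causal,
                         beta_eqtl, b_xy: float, n_eqtl: int,
                         n_gwas: int, rng: np.random.Generator,
                         pleiotropy: float = 0.0, pleio_snp: int | None = None
                         ) -> pd.DataFrame:
    """Fast single-locus instrument statistics for calibration experiments.

    Returns a table with columns snp_id, b_zx, se_zx, p_zx, b_zy, se_zy,
    p_zy for the SNPs ``snp_indices`` of ``panel``.  ``causal`` (one index
    into ``snp_indices``, or a list of them, paired with scalar or
    per-causal ``beta_eqtl``) defines the genetic component of expression;
    ``pleio_snp`` adds a direct liability effect.  The GWAS side regresses
    the continuous liability (linear model), keeping b_zy on the liability
    scale so the mediation identity b_zy = b_xy * b_zx holds exactly.
    """
    snp_indices = np.asarray(snp_indices, dtype=int)
    causal = np.atleast_1d(np.asarray(causal, dtype=int))
    betas = np.broadcast_to(np.asarray(beta_eqtl, dtype=float), causal.shape)
    cols = panel.dosages[:, snp_indices]
    causal_cols = cols[:, causal].astype(float)
    # population SD of the genetic + residual expression components
    sd_x = np.sqrt((betas[None, :] * causal_cols).sum(axis=1).var() + 1.0)

    geno_e = cols[rng.integers(0, panel.n_individuals, size=n_eqtl)]
    x = geno_e[:, causal] @ betas + rng.standard_normal(n_eqtl)
    x = (x - x.mean()) / x.std(ddof=1)
    b_zx, se_zx, p_zx = _linear_assoc(x, geno_e)

    geno_g = cols[rng.integers(0, panel.n_individuals, size=n_gwas)]
    liab = b_xy * (geno_g[:, causal] @ betas) / sd_x
    if pleiotropy != 0.0 and pleio_snp is not None:
        liab = liab + pleiotropy * geno_g[:, pleio_snp]
    liab = liab + rng.standard_normal(n_gwas)
    b_zy, se_zy, p_zy = _linear_assoc(liab, geno_g)

    return pd.DataFrame({
        "snp_id": [panel.snp_ids[j] for j in snp_indices],
        "b_zx": b_zx, "se_zx": se_zx, "p_zx": p_zx,
        "b_zy": b_zy, "se_zy": se_zy, "p_zy": p_zy,
    })


def make_gene_sets(config: SimulationConfig, truth: TruthTable, n_random: int = 20,
                   set_size: int = 50, rng: np.random.Generator | None = None
                   ) -> dict:
    """GMT-style gene sets: random sets plus the planted response genes."""
    rng = rng if rng is not None else stage_rng(config.seed, "gsea")
    genes = np.array(config.gene_ids())
    up = [g for g, eff in truth.response_effects.items() if eff > 0]
    down = [g for g, eff in truth.response_effects.items() if eff < 0]
    # sign-split: response signs are random, so only directional sets are
    # detectable by a running-sum enrichment
    sets = {"PLANTED_RESPONSE_UP": up,
            "PLANTED_RESPONSE_DOWN": down,
            "PLANTED_DIFF_RESPONSE": list(truth.diff_response_genes)}
    for i in range(n_random):
        sets[f"RANDOM_{i:03d}"] = list(rng.choice(genes, size=set_size,
                                                  replace=False))
    return sets
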