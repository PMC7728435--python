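"""Per-individual glucose response and moderated response testing.

The response of individual *i* at gene *k* is ``delta = mean(HG) - mean(SG)``
over replicates (log2 units).  Gene-level tests shrink the per-gene sample
variances toward a common prior by empirical Bayes (scaled inverse
chi-square prior with moment-matched ``d0`` and ``s0^2``), which gives the
moderated t-statistics used for both the all-individuals response test and
the two-group differential-response test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_qvalues, inv_trigamma
from .errors import ConfigError, DataError

__all__ = [
    "ExpressionMatrix",
    "ResponseMatrix",
    "ModerationPrior",
    "filter_detected_genes",
    "compute_response",
    "fit_moderation_prior",
    "test_response_all",
    "test_differential_response",
    "interindividual_variance_test",
    "pca_covariate_association",
]

log = logging.getLogger(__name__)

CONDITIONS = ("SG", "HG")


@dataclass
class ExpressionMatrix:
    """Replicate-level log2 expression with sample annotations.

    ``values``: genes x samples; ``samples``: per-sample annotation frame
    indexed by sample id with columns individual, replicate, condition,
    group; ``detection_p``: optional genes x samples detection p-values.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self):
        required = {"individual", "replicate", "condition", "group"}
        missing = required - set(self.samples.columns)
        if missing:
            raise DataError(f"sample annotation missing columns {sorted(missing)}")
        if list(self.values.columns) != list(self.samples.index):
            raise DataError("values columns must match sample annotation index")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise DataError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataError("expression values must be finite")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise DataError("detection_p must match values shape")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset_genes(self, genes) -> "ExpressionMatrix":
        det = self.detection_p.loc[genes] if self.detection_p is not None else None
        return ExpressionMatrix(self.values.loc[genes], self.samples, det)

    def to_long(self) -> pd.DataFrame:
        long = (self.values
                .rename_axis("gene_id")
                .reset_index()
                .melt(id_vars="gene_id", var_name="sample", value_name="log2_expr"))
        ann = self.samples.rename_axis("sample").reset_index()
        long = long.merge(ann, on="sample")
        long = long.rename(columns={"individual": "individual_id"})
        return long[["gene_id", "individual_id", "replicate", "condition",
                     "group", "log2_expr"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ExpressionMatrix":
        required = {"gene_id", "individual_id", "replicate", "condition",
                    "group", "log2_expr"}
        missing = required - set(long.columns)
        if missing:
            raise DataError(f"long table missing columns {sorted(missing)}")
        long = long.copy()
        long["sample"] = (long["individual_id"].astype(str) + "_"
                          + long["condition"].astype(str) + "_r"
                          + long["replicate"].astype(str))
        values = long.pivot(index="gene_id", columns="sample", values="log2_expr")
        ann = (long.drop_duplicates("sample")
               .set_index("sample")[["individual_id", "replicate", "condition",
                                     "group"]]
               .rename(columns={"individual_id": "individual"}))
        ann = ann.loc[values.columns]
        return cls(values=values, samples=ann)


@dataclass
class ResponseMatrix:
    """Per-gene, per-individual glucose response (HG - SG, log2 units)."""

    delta: pd.DataFrame            # genes x individuals
    groups: pd.Series              # individual -> group label

    def __post_init__(self):
        if set(self.delta.columns) - set(self.groups.index):
            raise DataError("every individual needs a group label")

    def individuals_in(self, group: str) -> list:
        return [i for i in self.delta.columns if self.groups[i] == group]


@dataclass
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 may be math.inf for full shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ConfigError("d0 must be positive (may be inf)")
        if not (self.s0_sq > 0):
            raise ConfigError("s0_sq must be positive")


def filter_detected_genes(expr: ExpressionMatrix, alpha: float = 0.01,
                          min_fraction: float = 0.0) -> ExpressionMatrix:
    """Keep genes detected (detection p < alpha) in enough samples.

    ``min_fraction`` is the required fraction of samples; the default keeps
    a gene detected in at least one sample.  Without detection p-values the
    matrix passes through unchanged (with a warning).
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    if not (0.0 <= min_fraction <= 1.0):
        raise ConfigError("min_fraction must be in [0, 1]")
    if expr.detection_p is None:
        log.warning("no detection p-values; detection filter is a pass-through")
        return expr
    detected = (expr.detection_p.to_numpy() < alpha)
    frac = detected.mean(axis=1)
    need = max(min_fraction, 1.0 / expr.values.shape[1])  # >= 1 sample
    keep = expr.genes[frac >= need]
    log.info("detection filter kept %d/%d genes", len(keep), len(expr.genes))
    return expr.subset_genes(keep)


def compute_response(expr: ExpressionMatrix) -> ResponseMatrix:
    """Collapse replicates by mean, then delta = mean(HG) - mean(SG)."""
    ann = expr.samples
    means = {}
    for (ind, cond), cols in ann.groupby(["individual", "condition"],
                                         observed=True).groups.items():
        means[(ind, cond)] = expr.values[list(cols)].mean(axis=1)
    individuals = sorted({ind for ind, _ in means})
    usable, dropped = [], []
    for ind in individuals:
        if (ind, "HG") in means and (ind, "SG") in means:
            usable.append(ind)
        else:
            dropped.append(ind)
    if dropped:
        log.warning("dropping individuals missing a condition: %s", dropped)
    if not usable:
        raise DataError("no individual has both SG and HG samples")
    delta = pd.DataFrame(
        {ind: means[(ind, "HG")] - means[(ind, "SG")] for ind in usable},
        index=expr.genes)
    groups = (ann.drop_duplicates("individual")
              .set_index("individual")["group"].loc[usable])
    return ResponseMatrix(delta=delta, groups=groups)


def fit_moderation_prior(sample_variances, residual_df: float) -> ModerationPrior:
    """Moment-match a scaled inverse chi-square prior to observed variances.

    Works on ``e = log(s^2)``: solves ``trigamma(d0/2) = var(e) -
    trigamma(df/2)`` by Newton iteration; when the spread of log-variances
    is at or below pure sampling noise the prior degrees of freedom are
    infinite and ``s0^2`` is the geometric mean variance.
    """
    if residual_df <= 0:
        raise ConfigError("residual_df must be positive")
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size and (s2 <= 0).all():
        raise DataError("all sample variances are zero")
    s2 = s2[s2 > 0]
    if s2.size < 10:
        raise DataError("need at least 10 genes with positive variance")
    e = np.log(s2)
    df2 = residual_df / 2.0
    bias_df = float(special.digamma(df2) - np.log(df2))
    var_e = e.var(ddof=1)
    if var_e < 1e-12:
        # exactly equal variances: no sampling noise, take the common value
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e.mean())))
    evar = var_e - float(special.polygamma(1, df2))
    if evar <= 0:
        # spread at or below chi-square sampling noise: full shrinkage,
        # de-bias the log-scale mean for E[log chi2_df/df]
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e.mean() - bias_df)))
    d0 = 2.0 * inv_trigamma(evar)
    bias_d0 = float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    s0_sq = float(np.exp(e.mean() - bias_df + bias_d0))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def _moderated_t(effect: np.ndarray, s2: np.ndarray, df: float, stderr_unit: float,
                 prior: ModerationPrior) -> pd.DataFrame:
    """Shared moderated-t core.

    ``stderr_unit`` scales sqrt(posterior variance) into the standard error
    of ``effect`` (e.g. 1/sqrt(n) for a one-sample mean).
    """
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = np.sqrt(s2_post) * stderr_unit
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.where(effect == 0, 0.0, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "effect_log2fc": effect,
        "t": t,
        "pvalue": p,
        "qvalue": bh_qvalues(p),
        "s2_post": s2_post,
        "df_resid": df,
        "df_total": df_total,
    })


def test_response_all(resp: ResponseMatrix,
                      prior: ModerationPrior | None = None) -> pd.DataFrame:
    """One-sample moderated t of delta across all individuals, per gene."""
    delta = resp.delta.to_numpy()
    n = delta.shape[1]
    if n < 3:
        raise DataError("need at least 3 individuals")
    mean = delta.mean(axis=1)
    s2 = delta.var(axis=1, ddof=1)
    df = n - 1
    if prior is None:
        prior = fit_moderation_prior(s2, df)
    out = _moderated_t(mean, s2, df, 1.0 / np.sqrt(n), prior)
    out.index = resp.delta.index
    return out


def test_differential_response(resp: ResponseMatrix, group_a: str, group_b: str,
                               prior: ModerationPrior | None = None,
                               pairing: dict | None = None) -> pd.DataFrame:
    """Two-group moderated test of delta (reported effect: group_a - group_b).

    Unpaired mode pools the within-group variances; paired mode runs a
    one-sample moderated t on per-pair differences (``pairing`` maps
    group_a individuals to their group_b partners).
    """
    inds_a = resp.individuals_in(group_a)
    inds_b = resp.individuals_in(group_b)
    if not inds_a or not inds_b:
        known = sorted(set(resp.groups))
        raise DataError(f"unknown or empty group; available groups: {known}")

    if pairing is not None:
        missing = [(a, b) for a, b in pairing.items()
                   if a not in inds_a or b not in inds_b]
        if missing:
            raise DataError(f"pairing references missing individuals: {missing}")
        if len(pairing) < 3:
            raise DataError("need at least 3 pairs")
        diffs = np.column_stack([
            resp.delta[a].to_numpy() - resp.delta[b].to_numpy()
            for a, b in pairing.items()])
        n = diffs.shape[1]
        mean = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df = n - 1
        unit = 1.0 / np.sqrt(n)
    else:
        if len(inds_a) < 3 or len(inds_b) < 3:
            raise DataError("need at least 3 individuals per group")
        da = resp.delta[inds_a].to_numpy()
        db = resp.delta[inds_b].to_numpy()
        na, nb = da.shape[1], db.shape[1]
        mean = da.mean(axis=1) - db.mean(axis=1)
        s2 = ((na - 1) * da.var(axis=1, ddof=1)
              + (nb - 1) * db.var(axis=1, ddof=1)) / (na + nb - 2)
        df = na + nb - 2
        unit = np.sqrt(1.0 / na + 1.0 / nb)
    if prior is None:
        prior = fit_moderation_prior(s2, df)
    out = _moderated_t(mean, s2, df, unit, prior)
    out.index = resp.delta.index
    return out


def interindividual_variance_test(expr: ExpressionMatrix) -> tuple[float, float]:
    """Rank test: are within-individual response profiles more alike?

    Builds replicate-level response profiles by pairing HG replicate r with
    SG replicate r inside each individual, computes all pairwise Pearson
    correlations of the profiles, and compares within- vs between-individual
    correlations with a one-sided Mann-Whitney test (within greater).
    """
    ann = expr.samples
    profiles, owners = [], []
    for ind, sub in ann.groupby("individual"):
        hg = sub[sub["condition"] == "HG"].sort_values("replicate")
        sg = sub[sub["condition"] == "SG"].sort_values("replicate")
        n_pairs = min(len(hg), len(sg))
        if n_pairs < 2:
            continue
        for r in range(n_pairs):
            d = (expr.values[hg.index[r]] - expr.values[sg.index[r]]).to_numpy()
            profiles.append(d)
            owners.append(ind)
    if len(set(owners)) < 2:
        raise DataError("need >=2 replicate pairs for >=2 individuals")
    profiles = np.asarray(profiles)
    corr = np.corrcoef(profiles)
    within, between = [], []
    for i in range(len(owners)):
        for j in range(i + 1, len(owners)):
            (within if owners[i] == owners[j] else between).append(corr[i, j])
    stat, p = stats.mannwhitneyu(within, between, alternative="greater")
    return float(stat), float(p)


def pca_covariate_association(resp: ResponseMatrix, covariates: pd.DataFrame,
                              n_components: int = 5) -> pd.DataFrame:
    """Associate top response PCs with per-individual covariates.

    Continuous covariates use a simple linear model (Pearson test);
    categorical ones a one-way ANOVA.  Single-level covariates are skipped.
    Returns a tidy frame (pc, covariate, statistic, pvalue).
    """
    delta = resp.delta.to_numpy()
    individuals = list(resp.delta.columns)
    if len(individuals) < 3:
        raise DataError("need at least 3 individuals")
    covariates = covariates.loc[individuals]
    centered = delta - delta.mean(axis=1, keepdims=True)
    # PCs over individuals (genes are features)
    _, _, vt = np.linalg.svd(centered.T, full_matrices=False)
    k = min(n_components, vt.shape[0], len(individuals) - 1)
    scores = centered.T @ vt[:k].T         # individuals x k
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        if col.nunique() < 2:
            log.warning("covariate %r has a single level; skipped", name)
            continue
        numeric = pd.api.types.is_numeric_dtype(col) and col.nunique() > 2
        for pc in range(k):
            y = scores[:, pc]
            if numeric:
                res = stats.pearsonr(col.to_numpy(dtype=float), y)
                stat, p = res.statistic, res.pvalue
            else:
                groups = [y[(col == lvl).to_numpy()] for lvl in col.unique()]
                stat, p = stats.f_oneway(*groups)
            rows.append((pc + 1, name, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["pc", "covariate", "statistic", "pvalue"])
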