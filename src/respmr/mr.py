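"""Summary-data Mendelian randomization: SMR, HEIDI and multi-SNP tests.

Per instrument, the effect of exposure on outcome is ``b_xy = b_zy / b_zx``
with the chi-square(1) statistic ``T = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2)``.
HEIDI tests homogeneity of per-SNP ``b_xy`` across LD-linked instruments
(delta-method covariance, moment-matched weighted chi-square null);
multi-SNP SMR sums per-instrument T over an LD-pruned (r^2 < 0.2) set with
the null approximated through the eigenvalues of the r^2 matrix.  LD
utilities (signed r from a dosage panel, greedy pruning, proxy search) are
included.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import satterthwaite_p
from .errors import ConfigError, DataError

__all__ = [
    "LDMatrix",
    "SmrResult",
    "harmonize",
    "compute_ld",
    "prune_ld",
    "find_proxies",
    "smr_test",
    "heidi_test",
    "multi_snp_smr",
]

log = logging.getLogger(__name__)

AMBIGUOUS = {frozenset(("A", "T")), frozenset(("G", "C"))}

INSTRUMENT_COLUMNS = ["snp_id", "b_zx", "se_zx", "p_zx", "b_zy", "se_zy", "p_zy"]


@dataclass
class LDMatrix:
    """Signed LD correlation over a SNP list (unit diagonal, PSD-adjusted)."""

    snp_ids: list
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise DataError("r must be square over snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise DataError("r must be symmetric")

    def index_of(self, snps) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snps], dtype=int)
        except KeyError as exc:
            raise DataError(f"SNP not in LD matrix: {exc.args[0]!r}") from None

    def submatrix(self, snps) -> np.ndarray:
        idx = self.index_of(snps)
        return self.r[np.ix_(idx, idx)]


@dataclass
class SmrResult:
    b_xy: float
    se_xy: float | None
    t_smr: float
    p_smr: float
    n_instruments: int = 1
    heidi_p: float | None = None
    heidi_n: int | None = None
    multi_p: float | None = None
    top_snp: str | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def harmonize(eqtl_rows: pd.DataFrame, gwas_rows: pd.DataFrame) -> pd.DataFrame:
    """Join eQTL and GWAS summary rows on snp_id into an instrument table.

    GWAS effects are flipped when the effect alleles disagree;
    strand-ambiguous (A/T, G/C) SNPs are dropped with a log entry.  When the
    eQTL table carries no allele columns the effect alleles are assumed
    aligned.
    """
    eq = eqtl_rows.rename(columns={"beta": "b_zx", "se": "se_zx",
                                   "pvalue": "p_zx"}).copy()
    gw = gwas_rows.rename(columns={"beta": "b_zy", "se": "se_zy",
                                   "pvalue": "p_zy"}).copy()
    has_alleles = {"effect_allele", "other_allele"} <= set(eq.columns)
    gw_cols = ["snp_id", "b_zy", "se_zy", "p_zy", "effect_allele", "other_allele"]
    eq_cols = ["snp_id", "b_zx", "se_zx", "p_zx"]
    if has_alleles:
        eq_cols += ["effect_allele", "other_allele"]
    merged = eq[eq_cols].merge(gw[gw_cols], on="snp_id",
                               suffixes=("_zx", "_zy"))
    if merged.empty:
        raise DataError("no shared SNPs between eQTL and GWAS tables")

    ea = merged["effect_allele_zy" if has_alleles else "effect_allele"].str.upper()
    oa = merged["other_allele_zy" if has_alleles else "other_allele"].str.upper()
    ambiguous = [frozenset((a, b)) in AMBIGUOUS for a, b in zip(ea, oa)]
    n_drop = int(np.sum(ambiguous))
    if n_drop:
        log.info("dropping %d strand-ambiguous SNPs", n_drop)
    merged = merged[~np.asarray(ambiguous)].copy()
    if merged.empty:
        raise DataError("all shared SNPs were strand-ambiguous")

    if has_alleles:
        ea_zx = merged["effect_allele_zx"].str.upper()
        oa_zx = merged["other_allele_zx"].str.upper()
        ea_zy = merged["effect_allele_zy"].str.upper()
        oa_zy = merged["other_allele_zy"].str.upper()
        same = (ea_zx == ea_zy) & (oa_zx == oa_zy)
        flipped = (ea_zx == oa_zy) & (oa_zx == ea_zy)
        bad = ~(same | flipped)
        if bad.any():
            log.warning("dropping %d SNPs with irreconcilable alleles",
                        int(bad.sum()))
            merged = merged[~bad].copy()
            same, flipped = same[~bad], flipped[~bad]
        merged.loc[flipped, "b_zy"] = -merged.loc[flipped, "b_zy"]
    out = merged[INSTRUMENT_COLUMNS].reset_index(drop=True)
    out.attrs["n_ambiguous_dropped"] = n_drop
    if (out["se_zx"] <= 0).any() or (out["se_zy"] <= 0).any():
        raise DataError("standard errors must be positive")
    return out


def compute_ld(panel, snps, ridge: float = 1e-6) -> LDMatrix:
    """Pearson r of reference dosages; monomorphic SNPs are excluded."""
    idx = panel.index_of(snps)
    dos = panel.dosages[:, idx].astype(float)
    sd = dos.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [snps[i] for i in np.flatnonzero(~keep)]
        log.warning("excluding %d monomorphic SNPs: %s", len(dropped), dropped[:5])
    snps = [s for s, k in zip(snps, keep) if k]
    if not snps:
        raise DataError("no polymorphic SNPs left")
    r = np.corrcoef(dos[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    # ridge keeps the matrix PSD without disturbing the unit diagonal
    r = (r + ridge * np.eye(len(snps))) / (1.0 + ridge)
    return LDMatrix(snp_ids=list(snps), r=r)


def prune_ld(instruments: pd.DataFrame, ld: LDMatrix, r2_max: float = 0.2
             ) -> pd.DataFrame:
    """Greedy LD pruning: accept by ascending p_zx, reject pairs r^2 >= r2_max."""
    order = instruments.sort_values(["p_zx", "snp_id"], kind="mergesort")
    idx = ld.index_of(order["snp_id"])
    accepted: list[int] = []
    keep_rows = []
    for row, j in zip(order.index, idx):
        if all(ld.r[j, a] ** 2 < r2_max for a in accepted):
            accepted.append(j)
            keep_rows.append(row)
    out = instruments.loc[keep_rows]
    # exhaustive verification of the invariant on every call (cheap)
    sub = ld.submatrix(out["snp_id"])
    off = sub[~np.eye(len(sub), dtype=bool)]
    assert (off ** 2 < r2_max).all(), "pruning invariant violated"
    return out.reset_index(drop=True)


def find_proxies(snp: str, ld: LDMatrix, r2_min: float = 0.8) -> list:
    """SNPs with r^2 > r2_min to the query, best first (query excluded)."""
    j = ld.index_of([snp])[0]
    r2 = ld.r[j] ** 2
    order = np.argsort(-r2, kind="mergesort")
    return [ld.snp_ids[i] for i in order if i != j and r2[i] > r2_min]


def smr_test(instrument) -> SmrResult:
    """Single-instrument SMR: b_xy = b_zy / b_zx, chi-square(1) test."""
    b_zx = float(instrument["b_zx"])
    se_zx = float(instrument["se_zx"])
    b_zy = float(instrument["b_zy"])
    se_zy = float(instrument["se_zy"])
    if b_zx == 0.0:
        raise DataError("b_zx is zero: instrument has no exposure effect")
    if se_zx <= 0 or se_zy <= 0:
        raise DataError("standard errors must be positive")
    z_zx = b_zx / se_zx
    z_zy = b_zy / se_zy
    b_xy = b_zy / b_zx
    denom = z_zx ** 2 + z_zy ** 2
    t_smr = (z_zx ** 2 * z_zy ** 2) / denom if denom > 0 else 0.0
    p = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    se_xy = abs(b_xy) / np.sqrt(t_smr) if t_smr > 0 else None
    snp = instrument.get("snp_id") if hasattr(instrument, "get") else None
    return SmrResult(b_xy=b_xy, se_xy=se_xy, t_smr=float(t_smr), p_smr=p,
                     top_snp=snp)


def _heidi_select(instruments: pd.DataFrame, ld: LDMatrix,
                  p_zx_max: float, max_instruments: int,
                  r2_top_range: tuple) -> tuple[pd.DataFrame, int]:
    """Instrument selection around the top SNP (smallest p_zx)."""
    inst = instruments.sort_values(["p_zx", "snp_id"], kind="mergesort")
    top_row = inst.iloc[0]
    j_top = ld.index_of([top_row["snp_id"]])[0]
    rest = inst.iloc[1:]
    rest = rest[rest["p_zx"] < p_zx_max]
    if len(rest):
        r2_top = ld.r[ld.index_of(rest["snp_id"]), j_top] ** 2
        lo, hi = r2_top_range
        rest = rest[(r2_top >= lo) & (r2_top <= hi)]
    rest = rest.iloc[: max_instruments - 1]
    return pd.concat([top_row.to_frame().T, rest]), j_top


def heidi_test(instruments: pd.DataFrame, ld: LDMatrix,
               p_zx_max: float = 1.6e-3, max_instruments: int = 20,
               r2_top_range: tuple = (0.05, 0.9)
               ) -> tuple[float | None, float | None, int]:
    """Heterogeneity-in-dependent-instruments test for horizontal pleiotropy.

    The top instrument (smallest p_zx) anchors per-SNP effect differences
    ``d_i = b_xy,i - b_xy,top``; their covariance follows by first-order
    error propagation of (b_zx, b_zy) with LD correlation ``r`` between
    SNPs, T = sum z_d^2, and the null is the moment-matched weighted
    chi-square with weights from the correlation matrix of d.

    Returns ``(T, p, n_used)``; fewer than 3 usable instruments yields
    ``(None, None, n)`` rather than an exception.
    """
    if len(instruments) < 3:
        return None, None, len(instruments)
    sel, _ = _heidi_select(instruments, ld, p_zx_max, max_instruments,
                           r2_top_range)
    n = len(sel)
    if n < 3:
        return None, None, n
    b_zx = sel["b_zx"].to_numpy(dtype=float)
    se_zx = sel["se_zx"].to_numpy(dtype=float)
    b_zy = sel["b_zy"].to_numpy(dtype=float)
    se_zy = sel["se_zy"].to_numpy(dtype=float)
    r = ld.submatrix(sel["snp_id"])
    b_xy = b_zy / b_zx

    # cov(b_xy_i, b_xy_j) by the delta method; zx and zy errors independent
    cov_xy = (np.outer(se_zy, se_zy) * r
              + np.outer(b_xy, b_xy) * np.outer(se_zx, se_zx) * r) \
        / np.outer(b_zx, b_zx)
    d = b_xy[1:] - b_xy[0]
    cov_d = (cov_xy[1:, 1:] - cov_xy[1:, [0]] - cov_xy[[0], 1:] + cov_xy[0, 0])
    var_d = np.diag(cov_d).copy()
    if np.any(var_d <= 0):
        return None, None, n
    z_d = d / np.sqrt(var_d)
    t_heidi = float((z_d ** 2).sum())
    corr_d = cov_d / np.sqrt(np.outer(var_d, var_d))
    eig = np.linalg.eigvalsh((corr_d + corr_d.T) / 2.0)
    p = satterthwaite_p(t_heidi, eig)
    return t_heidi, p, n


def multi_snp_smr(instruments_pruned: pd.DataFrame, ld: LDMatrix,
                  r2_max: float = 0.2) -> tuple[float, float]:
    """Aggregate SMR over independent instruments: T = sum of per-SNP T.

    The null distribution is the weighted chi-square with weights given by
    the eigenvalues of the element-wise squared LD matrix (both z_zx and
    z_zy correlate through r), evaluated by Satterthwaite moment matching.
    A single instrument falls back to the plain SMR test (with a notice).
    """
    m = len(instruments_pruned)
    if m == 0:
        raise DataError("no instruments supplied")
    if m == 1:
        log.info("single instrument: falling back to smr_test")
        res = smr_test(instruments_pruned.iloc[0])
        return res.t_smr, res.p_smr
    sub = ld.submatrix(instruments_pruned["snp_id"])
    off = sub[~np.eye(m, dtype=bool)]
    if (off ** 2 >= r2_max).any():
        raise DataError(f"instruments are not pruned to r^2 < {r2_max}")
    t_total = 0.0
    for _, row in instruments_pruned.iterrows():
        t_total += smr_test(row).t_smr
    if t_total == 0.0:
        return 0.0, 1.0
    eig = np.linalg.eigvalsh(sub ** 2)
    return float(t_total), satterthwaite_p(t_total, eig)
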