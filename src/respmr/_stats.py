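"""Small shared statistical primitives.

These are deliberately minimal: BH adjustment delegates to statsmodels, the
rest are closed forms used by more than one module.
"""
from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

__all__ = [
    "bh_qvalues",
    "two_proportion_z",
    "satterthwaite_p",
    "inv_trigamma",
    "stage_rng",
]

# fixed sub-stream keys so every pipeline stage can be regenerated on its own
_STAGE_KEYS = {
    "panel": 11,
    "expression": 23,
    "summary": 37,
    "gwas": 41,
    "gsea": 53,
    "permutation": 67,
    "pipeline": 79,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one top-level seed."""
    try:
        key = _STAGE_KEYS[stage]
    except KeyError:
        raise ConfigError(f"unknown RNG stage {stage!r}; one of {sorted(_STAGE_KEYS)}")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, <=1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_proportion_z(k_a: int, n_a: int, k_b: int, n_b: int,
                     alternative: str = "two-sided") -> tuple[float, float]:
    """Pooled-variance two-proportion z-test.

    Returns ``(z, p)``. ``alternative='greater'`` tests prop_a > prop_b.
    """
    if n_a <= 0 or n_b <= 0:
        raise DataError("both groups must be nonempty")
    pa, pb = k_a / n_a, k_b / n_b
    pool = (k_a + k_b) / (n_a + n_b)
    se = np.sqrt(pool * (1.0 - pool) * (1.0 / n_a + 1.0 / n_b))
    if se == 0.0:
        z = 0.0
    else:
        z = (pa - pb) / se
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    return float(z), float(min(p, 1.0))


def satterthwaite_p(t_obs: float, eigvals) -> float:
    """Upper-tail p for a weighted chi-square sum by moment matching.

    ``sum_j lam_j chi2_1`` is approximated by a scaled chi-square with the
    same mean and variance. Adequate for alpha >= 1e-3; tails beyond that are
    approximate (documented trade-off vs exact quadratic-form inversion).
    """
    lam = np.asarray(eigvals, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    s1 = lam.sum()
    s2 = (lam ** 2).sum()
    scale = s2 / s1
    df = s1 ** 2 / s2
    if t_obs <= 0.0:
        return 1.0
    return float(stats.chi2.sf(t_obs / scale, df))


def inv_trigamma(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ConfigError("inv_trigamma requires y > 0")
    x = 0.5 + 1.0 / y  # good start for both tails
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * (1.0 + abs(x)):
            return x_new
        x = x_new
    return x
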