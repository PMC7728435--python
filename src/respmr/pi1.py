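"""Storey-style pi0/pi1 estimation for "true positive rate" summaries."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["Pi1Estimate", "estimate_pi0"]

log = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)

# below this many p-values the polynomial smoother is unstable; fall back
# to a single lambda = 0.5 (the 272-instrument use case)
SMOOTHER_MIN_M = 500


@dataclass
class Pi1Estimate:
    pi0: float
    pi1: float
    lambda_grid: list
    method: str
    m: int
    pi0_by_lambda: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_pi0(pvalues, lambda_grid=None, method: str = "smoother") -> Pi1Estimate:
    """Estimate the null proportion pi0 (and pi1 = 1 - pi0).

    ``pi0_hat(lambda) = #{p > lambda} / (m * (1 - lambda))``.  The
    "smoother" method fits a degree-3 least-squares polynomial to
    ``pi0_hat`` over the grid and evaluates it at the largest lambda (a
    deterministic stand-in for the qvalue spline); "fixed" uses a single
    lambda (default 0.5).  Estimates are clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("no p-values supplied")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must be finite and in [0, 1]")
    if method not in ("smoother", "fixed"):
        raise ConfigError("method must be 'smoother' or 'fixed'")
    m = p.size

    if method == "smoother" and m < SMOOTHER_MIN_M:
        log.warning("m=%d < %d: falling back to fixed lambda=0.5", m, SMOOTHER_MIN_M)
        method = "fixed"

    if method == "fixed":
        lam = 0.5 if lambda_grid is None else float(np.atleast_1d(lambda_grid)[0])
        if not (0.0 < lam < 1.0):
            raise ConfigError("lambda must be in (0, 1)")
        pi0 = (p > lam).sum() / (m * (1.0 - lam))
        grid = [lam]
        curve = [float(pi0)]
    else:
        grid = DEFAULT_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
        if grid.size < 4:
            raise ConfigError("smoother needs a lambda grid of length >= 4")
        if np.any((grid <= 0) | (grid >= 1)):
            raise ConfigError("lambda grid must lie in (0, 1)")
        curve = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
        coeffs = np.polyfit(grid, curve, deg=3)
        pi0 = float(np.polyval(coeffs, grid.max()))
        grid = list(map(float, grid))
        curve = list(map(float, curve))

    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Estimate(pi0=pi0, pi1=1.0 - pi0, lambda_grid=list(grid),
                       method=method, m=int(m), pi0_by_lambda=list(curve))
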