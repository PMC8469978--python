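"""Shared nonlinear least-squares machinery.

Thin wrapper around :func:`scipy.optimize.least_squares` that returns parameter
standard errors from the Gauss-Newton approximation of the covariance,
``cov = (J'J)^-1 * SSE / (n - p)``, and supports multi-start optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares


@dataclass
class LsqResult:
    params: np.ndarray
    se: np.ndarray
    sse: float
    n: int
    success: bool


def fit_least_squares(
    residuals: Callable[[np.ndarray], np.ndarray],
    x0: Sequence[float],
    bounds: tuple = (-np.inf, np.inf),
    starts: Sequence[Sequence[float]] | None = None,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
) -> LsqResult:
    """Minimise sum of squared residuals from one or more starting points."""
    best = None
    all_starts = [np.asarray(x0, dtype=float)]
    if starts:
        all_starts += [np.asarray(s, dtype=float) for s in starts]
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    for s in all_starts:
        s = np.minimum(np.maximum(s, lo + 0.0), hi - 0.0)
        try:
            res = least_squares(residuals, s, bounds=bounds, xtol=xtol, ftol=ftol,
                                gtol=1e-12, method="trf")
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise RuntimeError("least-squares optimisation failed from every start")
    sse, res = best
    n = res.fun.size
    p = res.x.size
    se = np.full(p, np.nan)
    if n > p:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * sse / (n - p)
            diag = np.diag(cov)
            se = np.sqrt(np.where(diag >= 0, diag, np.nan))
        except np.linalg.LinAlgError:
            pass
    return LsqResult(params=res.x.copy(), se=se, sse=sse, n=n, success=bool(res.success))


def f_test_nested(sse_simple: float, p_simple: int, sse_complex: float,
                  p_complex: int, n: int) -> tuple[float, float]:
    """Extra-sum-of-squares F-test between nested models.

    Returns (F, p).  A complex model that fails to improve the fit yields
    F <= 0 and p = 1.
    """
    from scipy.stats import f as f_dist

    df1 = p_complex - p_simple
    df2 = n - p_complex
    if df1 <= 0 or df2 <= 0:
        raise ValueError("invalid degrees of freedom for nested F-test")
    if sse_complex <= 0:
        return np.inf, 0.0
    F = ((sse_simple - sse_complex) / df1) / (sse_complex / df2)
    if F <= 0:
        return float(F), 1.0
    return float(F), float(f_dist.sf(F, df1, df2))
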