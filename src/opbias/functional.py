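"""Functional concentration-response analysis.

Implements the Hill fit (bottom fixed at basal = 1) and the two-step
operational-model procedure:

1. the system maximum ``E_MAX`` of a (construct, pathway) is characterised by
   a global simultaneous fit over the curves of designated internal-standard
   agonists (carbachol, oxotremorine and pilocarpine by default), a single
   ``E_MAX`` shared with per-curve (tau, pKA);
2. the operational model with ``E_MAX`` fixed is then fitted to each
   individual experiment, yielding per-experiment (tau, pKA) summarised as
   mean +- SD across independent experiments.

A caveat the fitter surfaces rather than hides: for unit-slope curves the
shared-``E_MAX`` likelihood is exactly flat above the largest apparent
maximum — any ceiling reproduces every Hill-shaped curve perfectly through a
compensating (tau, K_A).  ``fit_system_emax`` therefore scans the ``E_MAX``
profile explicitly, reports whether the ridge is flat, and returns the
smallest ceiling statistically adequate for the standards (the knee of the
profile).  When the true system ceiling is known from the study design it
should be passed directly to step 2.

A flatness (coupling) verdict compares the Hill model against a constant by
an extra-sum-of-squares F-test; non-responding curves are reported with
tau = 0 and no pKA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fitting import LsqResult, f_test_nested, fit_least_squares
from .models import (
    ConcResponseSeries,
    HillFit,
    OperationalFit,
    hill_response,
    hill_to_operational,
    operational_response,
)

__all__ = [
    "CouplingVerdict",
    "fit_hill",
    "flat_test",
    "fit_system_emax",
    "fit_operational",
    "fit_operational_panel",
    "SystemEmaxFit",
]

FLAT_ALPHA = 0.05
EMAX_SPREAD_MIN = 0.05  # minimum relative E'MAX spread among standards


@dataclass
class CouplingVerdict:
    coupled: bool
    p_value: float
    F_statistic: float

    @property
    def verdict(self) -> str:
        return "coupled" if self.coupled else "no coupling"


@dataclass
class SystemEmaxFit:
    system_Emax: float
    system_Emax_se: float
    per_ligand: dict  # "ligand:experiment" -> OperationalFit at the chosen E_MAX
    sse: float
    ridge_flat: bool = True
    profile_emax: np.ndarray = field(default_factory=lambda: np.array([]))
    profile_sse: np.ndarray = field(default_factory=lambda: np.array([]))


def _hill_start(x, y):
    top = float(max(np.max(y), 1.0 + 1e-6))
    mid = 1.0 + (top - 1.0) / 2.0
    above = np.nonzero(y >= mid)[0]
    xs = np.sort(np.unique(x))
    x_mid = x[above[0]] if above.size else xs[len(xs) // 2]
    return float(-math.log10(x_mid)), top


def fit_hill(series: ConcResponseSeries, check_flat: bool = True) -> HillFit:
    """Fit the Hill equation with bottom fixed at 1.

    Returns a :class:`HillFit`; when the response is statistically
    indistinguishable from flat the fit is flagged ``no_response`` with
    ``EmaxPrime`` pinned at 1.
    """
    x, y = series.pooled()
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations for a Hill fit")
    if check_flat:
        verdict = flat_test(series)
        if not verdict.coupled:
            return HillFit(pEC50=math.nan, EmaxPrime=1.0, nH=math.nan,
                           no_response=True, experiment_id=series.experiment_id)
    res = _hill_lsq(x, y)
    fit = HillFit(
        pEC50=float(res.params[0]), EmaxPrime=float(res.params[1]),
        nH=float(res.params[2]), pEC50_se=float(res.se[0]),
        EmaxPrime_se=float(res.se[1]), nH_se=float(res.se[2]),
        experiment_id=series.experiment_id,
    )
    ec50 = 10.0 ** (-fit.pEC50)
    if not (x.min() / 10.0 <= ec50 <= x.max() * 10.0):
        warnings.warn("fitted EC50 lies outside the tested concentration "
                      "window x10; estimate poorly constrained", stacklevel=2)
    return fit


def _hill_lsq(x, y) -> LsqResult:
    pec50_0, top0 = _hill_start(x, y)

    def resid(p):
        return hill_response(x, p[0], p[1], p[2]) - y

    return fit_least_squares(
        resid, [pec50_0, top0, 1.0],
        bounds=([0.0, 1.0, 0.05], [15.0, 1e4, 10.0]),
        starts=[[pec50_0 + 1.0, top0, 1.0], [pec50_0 - 1.0, top0, 1.0]],
    )


def flat_test(series: ConcResponseSeries) -> CouplingVerdict:
    """F-test of the Hill model against a constant response.

    Used both to detect non-coupled constructs (flat cAMP at receptor-Ga16
    fusions) and non-responding agonists (tau = 0 rows).
    """
    x, y = series.pooled()
    const = float(np.mean(y))
    sse0 = float(np.sum((y - const) ** 2))
    if sse0 <= 1e-30:  # perfectly constant input
        return CouplingVerdict(coupled=False, p_value=1.0, F_statistic=0.0)
    res = _hill_lsq(x, y)
    sse1 = min(res.sse, sse0)  # the Hill family only approximately nests the constant
    F, p = f_test_nested(sse0, 1, sse1, 3, x.size)
    return CouplingVerdict(coupled=p < FLAT_ALPHA, p_value=p, F_statistic=F)


def _fit_tau_pka(x, y, system_Emax: float, hill: HillFit,
                 baseline: str) -> LsqResult:
    """Operational fit of one curve at fixed E_MAX, started from the Hill fit."""
    try:
        op0 = hill_to_operational(
            HillFit(pEC50=hill.pEC50,
                    EmaxPrime=min(hill.EmaxPrime, 0.98 * system_Emax), nH=1.0),
            system_Emax, baseline=baseline)
        x0 = [math.log10(max(op0.tau, 1e-3)), op0.pKA]
    except ValueError:
        x0 = [0.0, hill.pEC50 if not math.isnan(hill.pEC50) else 7.0]

    def resid(p):
        return operational_response(x, system_Emax, 10.0 ** p[0], p[1],
                                    baseline=baseline) - y

    return fit_least_squares(resid, x0, bounds=([-6.0, 0.0], [6.0, 15.0]),
                             starts=[[x0[0] + 1.0, x0[1]], [x0[0] - 1.0, x0[1]]])


def fit_system_emax(panel: list[ConcResponseSeries],
                    baseline: str = "rebased",
                    n_grid: int = 40,
                    ceiling_factor: float = 5.0) -> SystemEmaxFit:
    """Step 1: shared system E_MAX over internal-standard curves.

    The panel must contain curves of at least two agonists with
    distinguishable apparent maxima on the same (construct, pathway); a
    single curve leaves E_MAX on the exact likelihood ridge
    ``E_MAX * tau / (tau + 1) = const`` and is refused.

    The SSE profile over E_MAX is scanned on a log grid from just above the
    largest apparent maximum to ``ceiling_factor`` times it.  The returned
    ``system_Emax`` is the profile knee — the smallest ceiling whose SSE is
    within one residual-variance unit of the flat minimum; ``ridge_flat``
    records whether the upper end of the profile is equally adequate (it is,
    for unit-slope data, in which case the estimate is a lower bound on the
    true ceiling and its SE is reported as NaN).
    """
    if len(panel) < 2:
        raise ValueError("global E_MAX fit needs >= 2 internal-standard curves "
                         "(single-curve input leaves E_MAX on a ridge)")
    names = {s.ligand.name for s in panel}
    if len(names) < 2:
        raise ValueError("global E_MAX fit needs >= 2 distinct internal-standard "
                         "ligands")
    hills = [fit_hill(s, check_flat=False) for s in panel]
    tops = np.array([h.EmaxPrime for h in hills])
    # equi-efficacy guard on per-ligand mean apparent maxima (averaging over
    # experiments damps replicate noise)
    by_ligand: dict[str, list[float]] = {}
    for s, h in zip(panel, hills):
        by_ligand.setdefault(s.ligand.name, []).append(h.EmaxPrime)
    ligand_tops = np.array([np.mean(v) for v in by_ligand.values()])
    if (ligand_tops.max() - ligand_tops.min()) < EMAX_SPREAD_MIN * ligand_tops.mean():
        raise ValueError("E_MAX not identifiable from standards: apparent "
                         "maxima spread < 5% of their mean")
    data = [s.pooled() for s in panel]
    n = int(sum(x.size for x, _ in data))
    p = 1 + 2 * len(panel)

    grid = np.geomspace(tops.max() * 1.01, tops.max() * ceiling_factor, n_grid)

    def profile(emax: float) -> tuple[float, list[LsqResult]]:
        fits = [_fit_tau_pka(x, y, emax, h, baseline)
                for (x, y), h in zip(data, hills)]
        return float(sum(f.sse for f in fits)), fits

    sses = np.array([profile(e)[0] for e in grid])
    sse_flat = float(sses[-1])
    tol = sse_flat * (1.0 + 1.0 / max(n - p, 1))
    adequate = np.nonzero(sses <= tol)[0]
    knee_idx = int(adequate[0]) if adequate.size else int(np.argmin(sses))
    emax_hat = float(grid[knee_idx])
    ridge_flat = bool(sses[-1] <= sses[knee_idx] * (1.0 + 1e-6) + 1e-30)
    sse_hat, fits = profile(emax_hat)

    per_ligand: dict[str, OperationalFit] = {}
    for s, f in zip(panel, fits):
        lt, pka = f.params
        per_ligand[f"{s.ligand.name}:{s.experiment_id}"] = OperationalFit(
            system_Emax=emax_hat, tau=float(10.0 ** lt), pKA=float(pka),
            tau_se=float(10.0 ** lt * math.log(10.0) * f.se[0]),
            pKA_se=float(f.se[1]), emax_source="global_step1",
            baseline=baseline, experiment_id=s.experiment_id,
        )
    se = math.nan
    if not ridge_flat:
        # crude profile curvature SE: half-width of the adequate region
        hi = grid[adequate[-1]] if adequate.size else grid[-1]
        se = float((hi - emax_hat) / 2.0)
    return SystemEmaxFit(system_Emax=emax_hat, system_Emax_se=se,
                         per_ligand=per_ligand, sse=sse_hat,
                         ridge_flat=ridge_flat, profile_emax=grid,
                         profile_sse=sses)


def fit_operational(series: ConcResponseSeries, system_Emax: float,
                    baseline: str = "rebased") -> OperationalFit:
    """Step 2: operational fit of one experiment with E_MAX fixed.

    Flat series are reported with tau = 0 and pKA absent (not calculated),
    the convention used for agonists that do not stimulate the pathway.
    """
    verdict = flat_test(series)
    if not verdict.coupled:
        return OperationalFit(system_Emax=system_Emax, tau=0.0, pKA=None,
                              emax_source="fixed_input", baseline=baseline,
                              experiment_id=series.experiment_id)
    x, y = series.pooled()
    hill = fit_hill(series, check_flat=False)
    res = _fit_tau_pka(x, y, system_Emax, hill, baseline)
    lt, pka = res.params
    tau = float(10.0 ** lt)
    return OperationalFit(
        system_Emax=system_Emax, tau=tau, pKA=float(pka),
        tau_se=float(tau * math.log(10.0) * res.se[0]),
        pKA_se=float(res.se[1]), emax_source="fixed_input", baseline=baseline,
        experiment_id=series.experiment_id,
    )


def fit_operational_panel(experiments: list[ConcResponseSeries],
                          system_Emax: float,
                          baseline: str = "rebased") -> dict:
    """Fit each experiment and summarise tau and pKA across experiments."""
    fits = [fit_operational(s, system_Emax, baseline=baseline)
            for s in experiments]
    taus = np.array([f.tau for f in fits], dtype=float)
    pkas = np.array([f.pKA if f.pKA is not None else np.nan for f in fits])
    n = len(fits)
    out = {
        "fits": fits,
        "n_experiments": n,
        "tau_mean": float(np.mean(taus)),
        "tau_sd": float(np.std(taus, ddof=1)) if n > 1 else math.nan,
    }
    if np.isfinite(pkas).any():
        out["pKA_mean"] = float(np.nanmean(pkas))
        out["pKA_sd"] = (float(np.nanstd(pkas, ddof=1))
                         if np.isfinite(pkas).sum() > 1 else math.nan)
    else:
        out["pKA_mean"] = None
        out["pKA_sd"] = None
    return out
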