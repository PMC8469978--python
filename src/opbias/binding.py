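"""Radioligand binding analysis.

Saturation binding: specific binding is computed per concentration as the
replicate-averaged difference total - nonspecific, converted to molar bound
sites; the free radioligand concentration is the added concentration minus the
bound (ligand-depletion bookkeeping).  A rectangular hyperbola is then fitted
to (free, specific), yielding pKD and B_MAX (pmol sites / mg protein).

Competition binding: one- and two-site displacement models are both fitted to
percent-of-control data and compared by the extra-sum-of-squares F-test at
alpha = 0.05; IC50s are converted to inhibition constants with the
Cheng-Prusoff correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._fitting import f_test_nested, fit_least_squares
from .models import (
    CompetitionFit,
    ConcResponseSeries,
    SaturationFit,
    SaturationSeries,
    cheng_prusoff_pki,
    one_site_competition,
    saturation_specific,
    two_site_competition,
)

__all__ = [
    "SpecificBinding",
    "specific_binding",
    "fit_saturation",
    "fit_competition",
    "summarize_competition_fits",
]

TWO_SITE_ALPHA = 0.05
INCOMPLETE_INHIBITION_PCT = 20.0


@dataclass
class SpecificBinding:
    """Per-point specific binding with depletion-corrected free concentration."""

    free_conc_M: np.ndarray
    specific_conc_M: np.ndarray
    specific_dpm: np.ndarray
    excluded: np.ndarray  # mask of points dropped (nonspecific > total)


def specific_binding(series: SaturationSeries) -> SpecificBinding:
    """Average replicates, subtract nonspecific, and deplete the free pool.

    Points where the averaged nonspecific exceeds total are flagged and
    excluded with a warning.  A non-positive free concentration anywhere is a
    hard error: depletion is then too severe for the hyperbolic model.
    """
    total = np.nanmean(series.total_dpm, axis=1)
    nonspec = np.nanmean(series.nonspecific_dpm, axis=1)
    spec_dpm = total - nonspec
    excluded = spec_dpm < 0
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} saturation point(s) with nonspecific > total "
            "excluded from the fit", stacklevel=2)
    spec_conc = series.dpm_to_molar(np.where(excluded, 0.0, spec_dpm))
    added = series.added_conc_pM * 1e-12
    free = added - spec_conc
    if np.any(free[~excluded] <= 0):
        raise ValueError(
            "free radioligand concentration <= 0 after depletion correction; "
            "data violate the simple hyperbolic binding model")
    return SpecificBinding(free_conc_M=free, specific_conc_M=spec_conc,
                           specific_dpm=spec_dpm, excluded=excluded)


def fit_saturation(series: SaturationSeries) -> SaturationFit:
    """Fit the saturation hyperbola and report pKD and B_MAX (pmol/mg)."""
    sb = specific_binding(series)
    keep = ~sb.excluded
    free = sb.free_conc_M[keep]
    spec = sb.specific_conc_M[keep]
    if keep.sum() < 4:
        raise ValueError("need at least 4 usable saturation points")
    if np.all(spec <= 0):
        raise ValueError("no specific binding detected; saturation fit refused")

    # fit on log-parameter scales (pKD, pBMAX) with unit-normalised residuals:
    # raw bound concentrations are ~1e-11 M, far below optimizer tolerances
    scale_y = float(spec.max())
    pbmax0 = float(-math.log10(max(spec.max() * 1.2, 1e-15)))
    pkd0 = float(-math.log10(np.median(free)))

    def resid(p):
        return (saturation_specific(free, p[0], 10.0 ** (-p[1])) - spec) / scale_y

    res = fit_least_squares(
        resid, [pkd0, pbmax0],
        bounds=([3.0, 0.0], [15.0, 18.0]),
        starts=[[pkd0 + 1.0, pbmax0], [pkd0 - 1.0, pbmax0]],
    )
    pkd = res.params[0]
    bmax_conc = 10.0 ** (-res.params[1])
    bmax_se_conc = bmax_conc * math.log(10.0) * res.se[1]
    kd = 10.0 ** (-pkd)
    poorly = not (free.min() / 10.0 <= kd <= free.max() * 10.0)
    if poorly:
        warnings.warn("KD estimate poorly constrained by the tested "
                      "concentration window", stacklevel=2)
    # concentration-units BMAX -> pmol per mg protein
    scale = series.volume_l * 1e12 / series.protein_mg
    return SaturationFit(
        pKD=float(pkd), BMAX=float(bmax_conc * scale),
        pKD_se=float(res.se[0]), BMAX_se=float(bmax_se_conc * scale),
        poorly_constrained=poorly, experiment_id=series.experiment_id,
    )


def _fit_one_site(x, y):
    p0 = _pic50_guess(x, y)

    def resid(p):
        return one_site_competition(x, p[0]) - y

    return fit_least_squares(resid, [p0], bounds=([0.0], [15.0]),
                             starts=[[p0 - 1.0], [p0 + 1.0]])


def _pic50_guess(x, y) -> float:
    """Concentration at which the displacement curve crosses 50%."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    below = np.nonzero(ys <= 50.0)[0]
    if below.size:
        return float(-math.log10(xs[below[0]]))
    return float(-math.log10(np.median(xs)))


def _fit_two_site(x, y, one_site_pic50: float):
    # parameters: pIC50_high, log-separation (>=0), logit(f_low in [1,99]%)
    def unpack(p):
        p_high = p[0]
        p_low = p[0] - abs(p[1])
        f_low = 1.0 + 98.0 * expit(p[2])
        return p_high, p_low, f_low

    def resid(p):
        ph, pl, fl = unpack(p)
        return two_site_competition(x, ph, pl, fl) - y

    starts = [
        [one_site_pic50 + 0.7, 1.4, 0.0],
        [one_site_pic50 + 1.5, 3.0, 0.0],
        [one_site_pic50 + 0.2, 0.4, 0.0],
    ]
    res = fit_least_squares(resid, starts[0],
                            bounds=([0.0, 0.0, -6.0], [15.0, 8.0, 6.0]),
                            starts=starts[1:])
    ph, pl, fl = unpack(res.params)
    # delta-method SE for f_low from the logit parameter
    f_se = math.nan
    if not math.isnan(res.se[2]):
        f_se = 98.0 * expit(res.params[2]) * (1.0 - expit(res.params[2])) * res.se[2]
    se_high = res.se[0]
    se_low = math.hypot(res.se[0], res.se[1]) if not math.isnan(res.se[1]) else math.nan
    return res, (ph, pl, fl), (se_high, se_low, f_se)


def fit_competition(series: ConcResponseSeries, radioligand_conc: float = 1e-9,
                    radioligand_pKD: float = 9.0) -> CompetitionFit:
    """Fit one- and two-site displacement and select by F-test.

    ``series.responses`` must be percent of control binding.  The two-site
    model is retained only when the extra-sum-of-squares F-test rejects the
    one-site model at p < 0.05.  Each IC50 is Cheng-Prusoff corrected with the
    radioligand concentration and saturation-derived pKD.
    """
    x, y = series.pooled()
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct competitor concentrations")
    one = _fit_one_site(x, y)
    two, (ph, pl, fl), (se_h, se_l, se_f) = _fit_two_site(x, y, one.params[0])
    F, p = f_test_nested(one.sse, 1, two.sse, 3, x.size)

    bottom = float(np.mean(y[x == x.max()]))
    incomplete = bottom > INCOMPLETE_INHIBITION_PCT
    if incomplete:
        warnings.warn("incomplete inhibition: bottom plateau above "
                      f"{INCOMPLETE_INHIBITION_PCT:.0f}% of control", stacklevel=2)

    def pki(pic50):
        return cheng_prusoff_pki(pic50, radioligand_conc, radioligand_pKD)

    if p < TWO_SITE_ALPHA:
        return CompetitionFit(
            model="two_site", pIC50_high=float(ph), pIC50_low=float(pl),
            f_low=float(fl), pKI_high=pki(ph), pKI_low=pki(pl),
            F_statistic=F, p_value=p,
            pIC50_high_se=float(se_h), pIC50_low_se=float(se_l),
            f_low_se=float(se_f), incomplete_inhibition=incomplete,
            experiment_id=series.experiment_id,
        )
    pic50 = float(one.params[0])
    return CompetitionFit(
        model="one_site", pIC50_high=math.nan, pIC50_low=pic50, f_low=100.0,
        pKI_high=math.nan, pKI_low=pki(pic50), F_statistic=F, p_value=p,
        pIC50_low_se=float(one.se[0]), incomplete_inhibition=incomplete,
        experiment_id=series.experiment_id,
    )


def summarize_competition_fits(fits: list[CompetitionFit]) -> dict:
    """Across-experiment mean +- SD of pKI values (log-scale averaging)."""
    if not fits:
        raise ValueError("no fits to summarize")
    low = np.array([f.pKI_low for f in fits], dtype=float)
    high = np.array([f.pKI_high for f in fits], dtype=float)
    out = {
        "n_experiments": len(fits),
        "pKI_low_mean": float(np.nanmean(low)),
        "pKI_low_sd": float(np.nanstd(low, ddof=1)) if len(fits) > 1 else math.nan,
    }
    if np.isfinite(high).any():
        out["pKI_high_mean"] = float(np.nanmean(high))
        out["pKI_high_sd"] = (float(np.nanstd(high, ddof=1))
                              if np.isfinite(high).sum() > 1 else math.nan)
    return out
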