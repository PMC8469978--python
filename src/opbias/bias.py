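"""Relative intrinsic activity, transduction coefficients and bias factors.

Relative intrinsic activity (RA_i) expresses an agonist's activity at one
receptor/pathway relative to a reference agonist (carbachol).  It is oriented
so that a more potent or more efficacious test agonist gives RA_i > 1:

    RA_i = (E'_MAX,a / EC50,a) / (E'_MAX,ref / EC50,ref)
         = (tau_a / K_A,a) / (tau_ref / K_A,ref)

(the two routes coincide for unit Hill slopes under the plain-ceiling
operational convention, tau/(1+tau) = E'_MAX/E_MAX).

Bias between two receptors (same ligand, same pathway) is quantified by the
transduction-coefficient contrast

    ddlog = Dlog(tau/K_A)_A - Dlog(tau/K_A)_B,
    Dlog(tau/K_A) = [log10 tau + pKA]_ligand - [log10 tau + pKA]_reference,

and reported as the bias factor 10^ddlog.

Group comparisons use one-way ANOVA followed by Tukey HSD (alpha = 0.05),
with concentration-like parameters compared on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .models import HillFit, OperationalFit

__all__ = [
    "RAiResult",
    "BiasFactorResult",
    "compute_RAi",
    "compute_RAi_table",
    "compute_bias_factor",
    "rank_constructs",
    "format_ranking",
    "compare_groups",
]

ALPHA = 0.05
TIE_REL_DIFF = 0.10  # fallback tie threshold without dispersion information

LN10 = math.log(10.0)

Fit = Union[HillFit, OperationalFit]


@dataclass
class RAiResult:
    ligand: str
    RAi: float
    RAi_sd: float
    log_RAi: Optional[float]
    route: str  # "emax_ec50" (Hill quantities) or "tau_ka" (operational)


@dataclass
class BiasFactorResult:
    ligand: str
    construct_a: str
    construct_b: str
    ddlog_tau_over_KA: Optional[float]
    bias_factor: Optional[float]

    @property
    def defined(self) -> bool:
        return self.bias_factor is not None


def _log_activity(fit: Fit) -> Optional[float]:
    """log10 of the activity index: E'/EC50 (Hill) or tau/K_A (operational)."""
    if isinstance(fit, HillFit):
        if fit.no_response:
            return None
        return math.log10(fit.EmaxPrime) + fit.pEC50
    if fit.tau <= 0 or fit.pKA is None:
        return None
    return math.log10(fit.tau) + fit.pKA


def _log_activity_var(fit: Fit) -> float:
    """Delta-method variance of the log10 activity index."""
    if isinstance(fit, HillFit):
        v = 0.0
        if not math.isnan(fit.EmaxPrime_se):
            v += (fit.EmaxPrime_se / (fit.EmaxPrime * LN10)) ** 2
        if not math.isnan(fit.pEC50_se):
            v += fit.pEC50_se**2
        return v
    v = 0.0
    if not math.isnan(fit.tau_se) and fit.tau > 0:
        v += (fit.tau_se / (fit.tau * LN10)) ** 2
    if fit.pKA_se is not None and not math.isnan(fit.pKA_se):
        v += fit.pKA_se**2
    return v


def compute_RAi(fit: Fit, reference: Fit, ligand: str = "") -> RAiResult:
    """RA_i of one agonist against the reference at the same construct.

    Hill fits outside the unit-slope tolerance are rejected (the E'/EC50 route
    presumes nH = 1); non-responding agonists get RA_i = 0.
    """
    route = "emax_ec50" if isinstance(fit, HillFit) else "tau_ka"
    if isinstance(fit, HillFit) and not fit.no_response and not fit.unit_slope:
        raise ValueError(
            f"RA_i via E'MAX/EC50 requires a unit Hill slope; got nH={fit.nH}")
    la_ref = _log_activity(reference)
    if la_ref is None:
        raise ValueError("reference ligand has no detectable response")
    la = _log_activity(fit)
    if la is None:
        return RAiResult(ligand=ligand, RAi=0.0, RAi_sd=0.0, log_RAi=None,
                         route=route)
    log_rai = la - la_ref
    var = _log_activity_var(fit) + _log_activity_var(reference)
    rai = 10.0**log_rai
    sd = rai * LN10 * math.sqrt(var)
    return RAiResult(ligand=ligand, RAi=rai, RAi_sd=sd, log_RAi=log_rai,
                     route=route)


def compute_RAi_table(fits: Mapping[str, Fit], reference: str) -> pd.DataFrame:
    """RA_i for every ligand in ``fits`` against ``fits[reference]``."""
    if reference not in fits:
        raise ValueError(f"reference ligand {reference!r} missing from fits")
    ref = fits[reference]
    rows = []
    for name, fit in fits.items():
        r = compute_RAi(fit, ref, ligand=name)
        rows.append({"ligand": name, "RAi": r.RAi, "RAi_sd": r.RAi_sd,
                     "log_RAi": r.log_RAi, "route": r.route,
                     "is_reference": name == reference})
    return pd.DataFrame(rows)


def compute_bias_factor(fits_a: Mapping[str, OperationalFit],
                        fits_b: Mapping[str, OperationalFit],
                        ligand: str, reference: str,
                        construct_a: str = "A",
                        construct_b: str = "B") -> BiasFactorResult:
    """Bias factor 10^ddlog(tau/K_A) of ``ligand`` for construct A over B."""
    vals = []
    for fits in (fits_a, fits_b):
        for name in (ligand, reference):
            if name not in fits:
                raise ValueError(f"missing operational fit for {name!r}")
            f = fits[name]
            v = f.log_tau_over_KA
            vals.append(v)
    if any(v is None for v in vals):
        return BiasFactorResult(ligand=ligand, construct_a=construct_a,
                                construct_b=construct_b,
                                ddlog_tau_over_KA=None, bias_factor=None)
    dlog_a = vals[0] - vals[1]
    dlog_b = vals[2] - vals[3]
    ddlog = dlog_a - dlog_b
    return BiasFactorResult(ligand=ligand, construct_a=construct_a,
                            construct_b=construct_b,
                            ddlog_tau_over_KA=ddlog, bias_factor=10.0**ddlog)


def _pooled_t_p(m1, s1, n1, m2, s2, n2) -> float:
    """Two-sided pooled-variance two-sample t-test from summary statistics."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 <= 0:
        return 0.0 if m1 != m2 else 1.0
    t = abs(m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return 2.0 * float(stats.t.sf(t, df))


def rank_constructs(rai: Mapping[str, float],
                    sd: Optional[Mapping[str, float]] = None,
                    n: int = 3) -> list[list[str]]:
    """Order constructs by descending RA_i, grouping statistical ties.

    Adjacent constructs in the descending order are merged into a tie group
    ("~") when a pooled two-sample t-test on the summary statistics (mean, SD,
    n per group) does not separate them at alpha = 0.05.  Without SDs a
    relative difference below 10% declares a tie.
    """
    if len(rai) < 2:
        raise ValueError("ranking needs RA_i for at least 2 constructs")
    order = sorted(rai, key=lambda k: rai[k], reverse=True)
    groups: list[list[str]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        a, b = rai[prev], rai[cur]
        if sd is not None:
            tied = _pooled_t_p(a, sd[prev], n, b, sd[cur], n) >= ALPHA
        else:
            denom = max(abs(b), 1e-300)
            tied = abs(a - b) / denom < TIE_REL_DIFF
        if tied:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    return groups


def format_ranking(groups: Sequence[Sequence[str]]) -> str:
    return " > ".join(" ~ ".join(g) for g in groups)


def compare_groups(groups: Mapping[str, Sequence[float]],
                   log_scale: bool = False) -> dict:
    """One-way ANOVA followed by Tukey HSD across named groups.

    Returns the ANOVA p-value and a DataFrame of pairwise Tukey comparisons
    with ``reject`` flags.  With fewer than 3 estimates in any group the
    flags are withheld (all False) with a warning field set.
    """
    import warnings as _w

    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if log_scale:
        arrays = [np.log10(a) for a in arrays]
    small = [k for k, a in zip(names, arrays) if a.size < 3]
    if small:
        _w.warn(f"groups with < 3 estimates: {small}; significance flags "
                "withheld", stacklevel=2)
        return {"anova_p": math.nan, "tukey": None, "flags_withheld": True}
    F, p = stats.f_oneway(*arrays)
    result = {"anova_p": float(p), "anova_F": float(F), "flags_withheld": False}
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * a.size for k, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    pairs = list(zip(*np.triu_indices(len(tk.groupsunique), 1)))
    tukey = pd.DataFrame({
        "group1": [tk.groupsunique[i] for i, _ in pairs],
        "group2": [tk.groupsunique[j] for _, j in pairs],
        "meandiff": tk.meandiffs,
        "p-adj": tk.pvalues,
        "reject": tk.reject,
    })
    if p >= ALPHA:
        # ANOVA gate: no post-hoc flags unless the omnibus test is significant
        tukey["reject"] = False
    result["tukey"] = tukey
    return result
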