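"""Domain containers and forward-model equations.

All pharmacological forward models used elsewhere in the package live here as
pure functions of scalar/array concentrations:

* rectangular-hyperbola saturation binding (specific bound vs free radioligand),
* one- and two-site competition binding with the Cheng-Prusoff correction,
* the Hill equation for fold-over-basal functional responses (bottom fixed at 1),
* the operational model of agonism (Black-Leff) with system maximum ``E_MAX``,
  operational efficacy ``tau`` and agonist equilibrium dissociation constant
  ``K_A``.

Concentration-like parameters are handled throughout as negative log10 molar
(pEC50, pKA, pKD, pKI, pIC50); concentrations themselves are molar.

Two baseline conventions exist for the operational model.  Functional data are
expressed fold over basal with bottom equal to 1, so the default ("rebased")
forward model is ``y = 1 + (E_MAX - 1) tau x / (K_A + (tau + 1) x)``.  The
"plain" convention uses the textbook ceiling ``y_max = E_MAX tau / (tau + 1)``
and the closed form ``tau = E'_MAX / (E_MAX - E'_MAX)``; it is the convention
under which published parameter tables for the muscarinic Ga16-fusion panel are
internally consistent, so it is used when reproducing such tables.  Both
conventions share ``pEC50 = pKA + log10(1 + tau)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Subtype",
    "Variant",
    "Pathway",
    "ReceptorConstruct",
    "Ligand",
    "ConcResponseSeries",
    "SaturationSeries",
    "SaturationFit",
    "CompetitionFit",
    "HillFit",
    "OperationalFit",
    "hill_response",
    "operational_response",
    "operational_apparent_max",
    "pec50_from_operational",
    "pka_from_pec50",
    "hill_to_operational",
    "operational_to_hill",
    "one_site_competition",
    "two_site_competition",
    "cheng_prusoff_pki",
    "saturation_specific",
    "NH_UNITY_TOL",
]

#: Tolerance on |nH - 1| inside which the Hill fit is treated as unit-slope,
#: permitting the closed-form Hill <-> operational transform and E'MAX/EC50
#: style relative-activity arithmetic.
NH_UNITY_TOL = 0.2

DPM_PER_CI = 2.22e12  # disintegrations per minute in one curie


class Subtype(str, enum.Enum):
    """Muscarinic acetylcholine receptor subtype."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"
    M5 = "M5"


class Variant(str, enum.Enum):
    """Receptor expression variant.

    ``fused`` denotes a covalent receptor-Galpha16 fusion protein (1:1
    stoichiometry, endogenous G proteins excluded); ``cotransfected`` denotes
    free Galpha16 co-expressed with the wild-type receptor.
    """

    wt = "wt"
    fused = "fused"
    cotransfected = "cotransfected"


class Pathway(str, enum.Enum):
    IPx = "IPx"
    cAMP = "cAMP"


@dataclass(frozen=True)
class ReceptorConstruct:
    subtype: Subtype
    variant: Variant
    pathway: Pathway

    def __post_init__(self) -> None:
        object.__setattr__(self, "subtype", Subtype(self.subtype))
        object.__setattr__(self, "variant", Variant(self.variant))
        object.__setattr__(self, "pathway", Pathway(self.pathway))

    @property
    def label(self) -> str:
        suffix = {"wt": "wt", "fused": "Ga16", "cotransfected": "+Ga16"}[
            self.variant.value
        ]
        return f"{self.subtype.value}_{suffix}" if suffix != "wt" else f"{self.subtype.value}_wt"


@dataclass(frozen=True)
class Ligand:
    name: str
    role: str = "test"  # "reference" or "test"
    is_radioligand: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("reference", "test"):
            raise ValueError(f"ligand role must be 'reference' or 'test', got {self.role!r}")


def _as_sorted_conc(conc: Sequence[float]) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("concentrations must be a non-empty 1-D sequence")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive (molar)")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be sorted strictly ascending")
    return c


@dataclass
class ConcResponseSeries:
    """Replicate responses versus molar concentration for one curve.

    ``responses`` has shape ``(n_concentrations, n_replicates)``; NaN marks a
    missing well.  Functional responses are fold over basal (basal = 1);
    competition-binding responses are percent of control radioligand binding.
    """

    construct: ReceptorConstruct
    ligand: Ligand
    concentrations: np.ndarray
    responses: np.ndarray
    basal: float = 1.0
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        self.concentrations = _as_sorted_conc(self.concentrations)
        r = np.asarray(self.responses, dtype=float)
        if r.ndim == 1:
            r = r[:, None]
        if r.shape[0] != self.concentrations.size:
            raise ValueError(
                f"responses first axis ({r.shape[0]}) must match number of "
                f"concentrations ({self.concentrations.size})"
            )
        self.responses = r
        if not self.basal > 0:
            raise ValueError("basal must be positive")

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[1]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (x, y) pairs, dropping NaN wells."""
        x = np.repeat(self.concentrations, self.n_replicates)
        y = self.responses.ravel()
        keep = ~np.isnan(y)
        return x[keep], y[keep]

    def means(self) -> np.ndarray:
        return np.nanmean(self.responses, axis=1)


@dataclass
class SaturationSeries:
    """Radioligand saturation-binding plate data.

    ``added_conc_pM`` is the nominal radioligand concentration per point;
    ``total_dpm`` and ``nonspecific_dpm`` are replicate matrices of shape
    ``(n_conc, n_rep)``.  The conversion constants turn dpm into molar bound
    ligand: ``bound_M = dpm / 2.22e12 / SA(Ci/mmol) * 1e-3 / volume_L``.
    """

    added_conc_pM: np.ndarray
    total_dpm: np.ndarray
    nonspecific_dpm: np.ndarray
    specific_activity_ci_mmol: float = 80.0
    counting_efficiency: float = 1.0
    protein_mg: float = 0.01
    volume_l: float = 8e-4
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        self.added_conc_pM = _as_sorted_conc(self.added_conc_pM)
        for name in ("total_dpm", "nonspecific_dpm"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim == 1:
                m = m[:, None]
            if m.shape[0] != self.added_conc_pM.size:
                raise ValueError(f"{name} rows must match number of concentrations")
            setattr(self, name, m)

    def dpm_to_molar(self, dpm):
        """Convert bound dpm to molar concentration of bound sites."""
        mol = np.asarray(dpm, dtype=float) / self.counting_efficiency / DPM_PER_CI \
            / self.specific_activity_ci_mmol * 1e-3
        return mol / self.volume_l

    def molar_to_dpm(self, conc_m):
        mol = np.asarray(conc_m, dtype=float) * self.volume_l
        return mol * 1e3 * self.specific_activity_ci_mmol * DPM_PER_CI \
            * self.counting_efficiency


@dataclass
class SaturationFit:
    pKD: float
    BMAX: float  # pmol binding sites per mg membrane protein
    pKD_se: float = math.nan
    BMAX_se: float = math.nan
    poorly_constrained: bool = False
    experiment_id: str = "exp1"


@dataclass
class CompetitionFit:
    model: str  # "one_site" | "two_site"
    pIC50_high: float
    pIC50_low: float
    f_low: float  # percent of low-affinity sites; 100 for one_site
    pKI_high: float
    pKI_low: float
    F_statistic: float
    p_value: float
    pIC50_high_se: float = math.nan
    pIC50_low_se: float = math.nan
    f_low_se: float = math.nan
    incomplete_inhibition: bool = False
    experiment_id: str = "exp1"


@dataclass
class HillFit:
    pEC50: float
    EmaxPrime: float
    nH: float
    pEC50_se: float = math.nan
    EmaxPrime_se: float = math.nan
    nH_se: float = math.nan
    no_response: bool = False
    experiment_id: str = "exp1"

    @property
    def unit_slope(self) -> bool:
        return abs(self.nH - 1.0) <= NH_UNITY_TOL


@dataclass
class OperationalFit:
    system_Emax: float
    tau: float
    pKA: Optional[float]
    tau_se: float = math.nan
    pKA_se: float = math.nan
    emax_source: str = "fixed_input"  # "global_step1" | "fixed_input"
    baseline: str = "rebased"  # convention used to interpret E_MAX
    experiment_id: str = "exp1"

    @property
    def log_tau_over_KA(self) -> Optional[float]:
        """Transduction coefficient log10(tau/K_A)."""
        if self.tau <= 0 or self.pKA is None:
            return None
        return math.log10(self.tau) + self.pKA


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def hill_response(x, pEC50: float, EmaxPrime: float, nH: float = 1.0):
    """Hill concentration-response with bottom fixed at basal (=1).

    ``y = 1 + (E'_MAX - 1) x^nH / (EC50^nH + x^nH)``
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    if not nH > 0:
        raise ValueError("Hill coefficient nH must be positive")
    if EmaxPrime < 1:
        raise ValueError("EmaxPrime must be >= 1 for stimulatory fold-over-basal data")
    ec50 = 10.0 ** (-pEC50)
    xn = np.power(x, nH)
    out = 1.0 + (EmaxPrime - 1.0) * xn / (ec50**nH + xn)
    return out if out.ndim else float(out)


def operational_response(x, system_Emax: float, tau: float, pKA: float,
                         baseline: str = "rebased"):
    """Operational-model concentration-response.

    rebased (default): ``y = 1 + (E_MAX - 1) tau x / (K_A + (tau + 1) x)``
    plain:             ``y = E_MAX tau x / (K_A + (tau + 1) x)``
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    if not tau > 0:
        raise ValueError("operational efficacy tau must be positive")
    ka = 10.0 ** (-pKA)
    core = tau * x / (ka + (tau + 1.0) * x)
    if baseline == "rebased":
        out = 1.0 + (system_Emax - 1.0) * core
    elif baseline == "plain":
        out = system_Emax * core
    else:
        raise ValueError(f"unknown baseline convention {baseline!r}")
    return out if out.ndim else float(out)


def operational_apparent_max(system_Emax: float, tau: float,
                             baseline: str = "rebased") -> float:
    """Agonist apparent maximum E'_MAX implied by (E_MAX, tau)."""
    frac = tau / (tau + 1.0)
    if baseline == "rebased":
        return 1.0 + (system_Emax - 1.0) * frac
    if baseline == "plain":
        return system_Emax * frac
    raise ValueError(f"unknown baseline convention {baseline!r}")


def pec50_from_operational(pKA: float, tau: float) -> float:
    """EC50 = K_A / (1 + tau), hence pEC50 = pKA + log10(1 + tau)."""
    return pKA + math.log10(1.0 + tau)


def pka_from_pec50(pEC50: float, tau: float) -> float:
    """Inverse of :func:`pec50_from_operational`."""
    return pEC50 - math.log10(1.0 + tau)


def hill_to_operational(hill: HillFit, system_Emax: float,
                        baseline: str = "rebased") -> OperationalFit:
    """Closed-form Hill -> operational transform (valid for unit slope).

    rebased: ``tau = (E'_MAX - 1) / (E_MAX - E'_MAX)``
    plain:   ``tau = E'_MAX / (E_MAX - E'_MAX)``
    and in both conventions ``pKA = pEC50 - log10(1 + tau)``.
    """
    if not hill.unit_slope:
        raise ValueError(
            f"closed-form transform requires |nH - 1| <= {NH_UNITY_TOL}; got nH={hill.nH}"
        )
    if hill.EmaxPrime >= system_Emax:
        raise ValueError(
            "non-identifiable: apparent maximum E'_MAX="
            f"{hill.EmaxPrime} reaches the system ceiling E_MAX={system_Emax}; "
            "tau is unbounded"
        )
    if baseline == "rebased":
        tau = (hill.EmaxPrime - 1.0) / (system_Emax - hill.EmaxPrime)
    elif baseline == "plain":
        tau = hill.EmaxPrime / (system_Emax - hill.EmaxPrime)
    else:
        raise ValueError(f"unknown baseline convention {baseline!r}")
    pka = pka_from_pec50(hill.pEC50, tau)
    # first-order SE propagation where the Hill SEs are available
    tau_se = math.nan
    pka_se = math.nan
    if not math.isnan(hill.EmaxPrime_se):
        # d tau / d E' = (E_MAX - c) / (E_MAX - E')^2 with c = 1 (rebased) or 0
        c = 1.0 if baseline == "rebased" else 0.0
        dtau = (system_Emax - c) / (system_Emax - hill.EmaxPrime) ** 2
        tau_se = abs(dtau) * hill.EmaxPrime_se
    if not math.isnan(hill.pEC50_se):
        var = hill.pEC50_se**2
        if not math.isnan(tau_se):
            dpka_dtau = -1.0 / ((1.0 + tau) * math.log(10.0))
            var += (dpka_dtau * tau_se) ** 2
        pka_se = math.sqrt(var)
    return OperationalFit(
        system_Emax=system_Emax, tau=tau, pKA=pka, tau_se=tau_se, pKA_se=pka_se,
        emax_source="fixed_input", baseline=baseline, experiment_id=hill.experiment_id,
    )


def operational_to_hill(op: OperationalFit) -> HillFit:
    """Forward map (E_MAX, tau, pKA) -> (pEC50, E'_MAX, nH=1)."""
    if op.tau <= 0 or op.pKA is None:
        raise ValueError("operational fit has no response (tau = 0)")
    return HillFit(
        pEC50=pec50_from_operational(op.pKA, op.tau),
        EmaxPrime=operational_apparent_max(op.system_Emax, op.tau, op.baseline),
        nH=1.0,
        experiment_id=op.experiment_id,
    )


def one_site_competition(x, pIC50: float):
    """Percent of control radioligand binding vs competitor concentration."""
    x = np.asarray(x, dtype=float)
    ic50 = 10.0 ** (-pIC50)
    out = 100.0 - 100.0 * x / (x + ic50)
    return out if out.ndim else float(out)


def two_site_competition(x, pIC50_high: float, pIC50_low: float, f_low: float):
    """Two-site competition; ``f_low`` is the percent of low-affinity sites."""
    if not 0.0 <= f_low <= 100.0:
        raise ValueError("f_low must lie in [0, 100] percent")
    x = np.asarray(x, dtype=float)
    ic_h = 10.0 ** (-pIC50_high)
    ic_l = 10.0 ** (-pIC50_low)
    out = (100.0
           - (100.0 - f_low) * x / (x + ic_h)
           - f_low * x / (x + ic_l))
    return out if out.ndim else float(out)


def cheng_prusoff_pki(pIC50: float, radioligand_conc: float,
                      radioligand_pKD: float) -> float:
    """Cheng-Prusoff correction: K_I = IC50 / (1 + [D]/K_D), log form.

    Returns pKI = pIC50 + log10(1 + [D]/K_D); with [D] = 0 the correction is
    the identity.
    """
    if radioligand_conc < 0:
        raise ValueError("radioligand concentration must be non-negative")
    kd = 10.0 ** (-radioligand_pKD)
    return pIC50 + math.log10(1.0 + radioligand_conc / kd)


def saturation_specific(x, pKD: float, bmax_conc: float):
    """Rectangular hyperbola: specific bound (conc units) vs free radioligand."""
    x = np.asarray(x, dtype=float)
    kd = 10.0 ** (-pKD)
    out = bmax_conc * x / (kd + x)
    return out if out.ndim else float(out)
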