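"""Virtual radioligand-binding and functional experiments.

The generator emulates the experimental designs the analysis modules assume,
for CHO cells expressing muscarinic receptor constructs:

* saturation binding: 6 radioligand concentrations spanning 63-2000 pM in
  quadruplicate, total and nonspecific (excess atropine) wells, with a linear
  nonspecific component and ligand depletion bookkeeping;
* competition binding: displacement of 1 nM radioligand, quadruplicate,
  one- or two-site ground truth;
* IPx accumulation: 9-point half-log concentration grids centred on the true
  pEC50, triplicate, responses generated at the dpm level over a basal drawn
  uniformly between 2 and 3% of incorporated radioactivity and re-expressed
  fold over basal;
* cAMP: biphasic (Gi/o inhibition at submicromolar + Gs stimulation at
  micromolar agonist) at wild-type M2/M4, flat at Ga16 fusions.

Noise is multiplicative Gaussian, parameterised by a coefficient of variation
(default 5% functional, 3% binding).  Each simulated quantity is fully
determined by the configuration seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import (
    ConcResponseSeries,
    Ligand,
    ReceptorConstruct,
    SaturationSeries,
    one_site_competition,
    operational_response,
    two_site_competition,
)

__all__ = [
    "SimulationConfig",
    "FunctionalTruth",
    "CompetitionTruth",
    "SaturationTruth",
    "simulate_saturation",
    "simulate_competition",
    "simulate_functional",
    "simulate_camp",
    "default_concentration_grid",
    "SATURATION_GRID_PM",
]

#: default saturation design: six concentrations spanning 63-2000 pM
SATURATION_GRID_PM = np.array([63.0, 125.0, 250.0, 500.0, 1000.0, 2000.0])


@dataclass
class SaturationTruth:
    pKD: float = 9.0
    BMAX_pmol_mg: float = 2.0
    nonspecific_fraction_per_nM: float = 0.2  # nonspecific/total at 1 nM free


@dataclass
class CompetitionTruth:
    pKI_low: float = 5.0
    pKI_high: Optional[float] = None
    f_low: float = 100.0  # percent of low-affinity sites

    @property
    def two_site(self) -> bool:
        return self.pKI_high is not None and 0.0 < self.f_low < 100.0


@dataclass
class FunctionalTruth:
    system_Emax: float = 30.7
    tau: float = 1.41
    pKA: float = 6.6
    responds: bool = True


@dataclass
class SimulationConfig:
    """Design constants and noise model for one virtual study.

    The defaults are the study conditions every simulation-based test runs
    under: 3 independent experiments, quadruplicate binding wells with 3% CV,
    triplicate functional wells with 5% CV, basal 2-3% of ~2e5 dpm
    incorporated radioactivity, 9-point half-log functional grids.
    """

    rng_seed: int = 0
    n_experiments: int = 3
    binding_replicates: int = 4
    functional_replicates: int = 3
    binding_cv: float = 0.03
    functional_cv: float = 0.05
    basal_fraction_range: tuple = (0.02, 0.03)
    incorporated_dpm: float = 2.0e5
    n_functional_conc: int = 9
    radioligand_conc: float = 1e-9

    def rng(self, *spawn_key: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=list(spawn_key))
        return np.random.default_rng(ss)


def default_concentration_grid(center_p: float, n: int = 9) -> np.ndarray:
    """Half-log molar grid of ``n`` points centred on 10^-center_p."""
    offsets = (np.arange(n) - (n - 1) / 2) * 0.5
    return 10.0 ** (-center_p + offsets)


def _mult_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    return 1.0 + cv * rng.standard_normal(shape)


def simulate_saturation(config: SimulationConfig,
                        truth: SaturationTruth = SaturationTruth(),
                        experiment: int = 0) -> tuple[SaturationSeries, dict]:
    """One saturation plate; returns the series and its ground truth record.

    Free concentration at each point solves the depletion balance
    free = added - bound(free) exactly (quadratic root), so the analysis
    module's depletion bookkeeping can be checked against ``truth_free_M``.
    """
    rng = config.rng(1, experiment)
    series = SaturationSeries(
        added_conc_pM=SATURATION_GRID_PM.copy(),
        total_dpm=np.zeros((SATURATION_GRID_PM.size, config.binding_replicates)),
        nonspecific_dpm=np.zeros((SATURATION_GRID_PM.size,
                                  config.binding_replicates)),
        experiment_id=f"exp{experiment + 1}",
    )
    kd = 10.0 ** (-truth.pKD)
    bmax_conc = truth.BMAX_pmol_mg * 1e-12 * series.protein_mg / series.volume_l
    added = series.added_conc_pM * 1e-12
    # bound = Bmax*free/(KD+free); free = added - bound  ->  quadratic in free
    b = kd + bmax_conc - added
    free = (-b + np.sqrt(b**2 + 4.0 * kd * added)) / 2.0
    bound = added - free
    # linear nonspecific component, slope set so nonspecific/total ~= the
    # requested fraction at 1 nM free radioligand
    bound_1nM = bmax_conc * 1e-9 / (kd + 1e-9)
    ns_slope = truth.nonspecific_fraction_per_nM * bound_1nM / (
        (1.0 - truth.nonspecific_fraction_per_nM) * 1e-9)
    nonspecific = ns_slope * free
    total = bound + nonspecific
    total_dpm = series.molar_to_dpm(total)
    ns_dpm = series.molar_to_dpm(nonspecific)
    shape = (added.size, config.binding_replicates)
    series.total_dpm = total_dpm[:, None] * _mult_noise(rng, shape, config.binding_cv)
    series.nonspecific_dpm = ns_dpm[:, None] * _mult_noise(rng, shape,
                                                           config.binding_cv)
    record = {
        "pKD": truth.pKD, "BMAX_pmol_mg": truth.BMAX_pmol_mg,
        "truth_free_M": free, "truth_bound_M": bound,
        "truth_nonspecific_M": nonspecific,
    }
    return series, record


def simulate_competition(config: SimulationConfig, ligand: str,
                         truth: CompetitionTruth = CompetitionTruth(),
                         construct: Optional[ReceptorConstruct] = None,
                         radioligand_pKD: float = 9.0,
                         experiment: int = 0,
                         concentrations: Optional[np.ndarray] = None,
                         ) -> tuple[ConcResponseSeries, dict]:
    """One competition curve (% of control binding vs competitor)."""
    rng = config.rng(2, experiment, zlib.crc32(ligand.encode()) % (2**31))
    shift = math.log10(1.0 + config.radioligand_conc / 10.0 ** (-radioligand_pKD))
    if concentrations is None:
        center = truth.pKI_low - shift  # pIC50 of the (dominant) low site
        concentrations = default_concentration_grid(center, 11)
    if truth.two_site:
        y = two_site_competition(concentrations, truth.pKI_high - shift,
                                 truth.pKI_low - shift, truth.f_low)
    else:
        y = one_site_competition(concentrations, truth.pKI_low - shift)
    shape = (concentrations.size, config.binding_replicates)
    responses = y[:, None] * _mult_noise(rng, shape, config.binding_cv)
    series = ConcResponseSeries(
        construct=construct or ReceptorConstruct("M2", "fused", "IPx"),
        ligand=Ligand(ligand), concentrations=concentrations,
        responses=responses, experiment_id=f"exp{experiment + 1}",
    )
    record = {"ligand": ligand, "pKI_low": truth.pKI_low,
              "pKI_high": truth.pKI_high, "f_low": truth.f_low,
              "pIC50_low": truth.pKI_low - shift,
              "pIC50_high": (truth.pKI_high - shift) if truth.two_site else None}
    return series, record


def simulate_functional(config: SimulationConfig, ligand: str,
                        truth: FunctionalTruth = FunctionalTruth(),
                        construct: Optional[ReceptorConstruct] = None,
                        experiment: int = 0,
                        concentrations: Optional[np.ndarray] = None,
                        ) -> tuple[ConcResponseSeries, dict]:
    """One IPx accumulation experiment expressed fold over basal.

    Responses are generated at the dpm level: a basal fraction is drawn
    uniformly in the 2-3% band of incorporated radioactivity, agonist wells
    are the re-based operational model times basal with multiplicative noise,
    and the series is normalised by the measured basal replicate mean
    (blank already subtracted), as plate data would be.
    """
    rng = config.rng(3, experiment, zlib.crc32(ligand.encode()) % (2**31))
    if concentrations is None:
        center = (truth.pKA + math.log10(1.0 + truth.tau)) if truth.responds \
            else 6.0
        concentrations = default_concentration_grid(center,
                                                    config.n_functional_conc)
    lo, hi = config.basal_fraction_range
    basal_dpm = rng.uniform(lo, hi) * config.incorporated_dpm
    if truth.responds:
        fold = operational_response(concentrations, truth.system_Emax,
                                    truth.tau, truth.pKA, baseline="rebased")
    else:
        fold = np.ones_like(concentrations)
    shape = (concentrations.size, config.functional_replicates)
    signal_dpm = basal_dpm * fold[:, None] * _mult_noise(
        rng, shape, config.functional_cv)
    basal_wells = basal_dpm * _mult_noise(rng, (config.functional_replicates,),
                                          config.functional_cv)
    responses = signal_dpm / float(np.mean(basal_wells))
    series = ConcResponseSeries(
        construct=construct or ReceptorConstruct("M2", "fused", "IPx"),
        ligand=Ligand(ligand), concentrations=concentrations,
        responses=responses, basal=float(np.mean(basal_wells)),
        experiment_id=f"exp{experiment + 1}",
    )
    record = {"ligand": ligand, "system_Emax": truth.system_Emax,
              "tau": truth.tau if truth.responds else 0.0,
              "pKA": truth.pKA if truth.responds else None,
              "basal_dpm": basal_dpm,
              "basal_fraction": basal_dpm / config.incorporated_dpm}
    return series, record


def simulate_camp(config: SimulationConfig, construct: ReceptorConstruct,
                  pIC50_inhibitory: float = 7.0, pEC50_stimulatory: float = 5.0,
                  inhibitory_amplitude: float = 0.5,
                  stimulatory_amplitude: float = 1.5,
                  experiment: int = 0,
                  concentrations: Optional[np.ndarray] = None,
                  ) -> tuple[ConcResponseSeries, dict]:
    """Agonist-modulated cAMP over a forskolin-stimulated basal of 1.

    Wild-type M2/M4 produce the biphasic sum of a descending Gi/o component
    (submicromolar IC50) and an ascending Gs component (micromolar EC50);
    Ga16-fused constructs are flat at 1 (no access for endogenous G proteins).
    """
    rng = config.rng(4, experiment, 0 if construct.variant.value == "wt" else 1)
    if concentrations is None:
        concentrations = default_concentration_grid(6.0, config.n_functional_conc)
    if construct.variant.value == "wt":
        ic50 = 10.0 ** (-pIC50_inhibitory)
        ec50 = 10.0 ** (-pEC50_stimulatory)
        fold = (1.0
                - inhibitory_amplitude * concentrations / (concentrations + ic50)
                + stimulatory_amplitude * concentrations / (concentrations + ec50))
        flat = False
    else:
        fold = np.ones_like(concentrations)
        flat = True
    shape = (concentrations.size, config.functional_replicates)
    responses = fold[:, None] * _mult_noise(rng, shape, config.functional_cv)
    series = ConcResponseSeries(
        construct=ReceptorConstruct(construct.subtype, construct.variant, "cAMP"),
        ligand=Ligand("carbachol", role="reference"),
        concentrations=concentrations, responses=responses,
        experiment_id=f"exp{experiment + 1}",
    )
    record = {"flat": flat, "pIC50_inhibitory": pIC50_inhibitory,
              "pEC50_stimulatory": pEC50_stimulatory,
              "truth_mean_curve": fold}
    return series, record
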