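"""Published parameter compilations for the muscarinic receptor-Ga16 panel.

Three small tables of literature operational-model and binding parameters for
muscarinic acetylcholine receptors (M1-M5) coupled to the promiscuous Galpha16
protein, with carbachol as the reference agonist:

* :func:`load_ga16_panel` — operational efficacy tau, pKA, relative intrinsic
  activity RA_i and system E_MAX per (receptor-Ga16 fusion, agonist) for the
  IPx pathway;
* :func:`load_m2_m5_variants` — Hill and operational parameters for M2 and M5
  as wild-type, Galpha16-cotransfected and Galpha16-fused variants;
* :func:`load_ga16_binding` — agonist pKI values from radioligand competition
  (one row per binding site; some agonists resolve high- and low-affinity
  sites).

These tables drive table-mode bias recomputation (no raw curves needed) and
provide realistic ground-truth parameters for the simulator.  SD columns are
across three independent experiments; significance flags: ``*`` greater than
at other subtypes / than the reference agonist, ``dagger`` different from the
fusion protein (ANOVA + Tukey HSD, p < 0.05).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_ga16_panel", "load_m2_m5_variants", "load_ga16_binding"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("opbias.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_ga16_panel() -> pd.DataFrame:
    """Operational parameters and RA_i for the five Ga16-fusion receptors."""
    return _read("ga16_panel_functional.csv")


def load_m2_m5_variants() -> pd.DataFrame:
    """Functional parameters for M2/M5 wild-type, cotransfected and fused."""
    return _read("m2_m5_variants_functional.csv")


def load_ga16_binding() -> pd.DataFrame:
    """Competition-binding pKI values at the Ga16-fusion receptors."""
    return _read("ga16_panel_binding.csv")
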