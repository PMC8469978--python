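"""End-to-end orchestration: simulate -> fit -> bias report.

A study configuration (plain dict, YAML-loadable) names either input CSVs or
a simulation spec, the reference ligand, and the internal-standard agonists
used for the step-1 global E_MAX fit.  ``run_pipeline`` executes the stages in
order — binding fits, Hill + two-step operational fits, RA_i/bias-factor
computation — writing parameter CSVs, a bias CSV, a polar plot and a run log.
Everything downstream of the seed is deterministic.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import compute_bias_factor, compute_RAi_table, format_ranking, rank_constructs
from .binding import fit_competition, fit_saturation, summarize_competition_fits
from .datasets import load_ga16_panel
from .functional import fit_hill, fit_operational, fit_system_emax, flat_test
from .io import (
    LongTable,
    read_long_csv,
    saturation_to_frame,
    series_to_frame,
)
from .models import HillFit, OperationalFit, ReceptorConstruct
from .simulate import (
    CompetitionTruth,
    FunctionalTruth,
    SaturationTruth,
    SimulationConfig,
    simulate_competition,
    simulate_functional,
    simulate_saturation,
)

__all__ = ["default_study", "simulate_study", "run_pipeline",
           "bias_from_params", "fit_functional_table"]

STANDARDS = ("carbachol", "oxotremorine", "pilocarpine")


def default_study(seed: int = 0) -> dict:
    """A compact virtual study: M2-Ga16 and M4-Ga16, IPx pathway.

    True parameters are the published panel values for the internal standards
    plus one non-responding agonist (JR7); binding truths come from the
    published pKI table where present.
    """
    panel = load_ga16_panel()

    def truths(receptor):
        sub = panel[panel.receptor == receptor].set_index("ligand")
        out = {}
        for lig in STANDARDS:
            row = sub.loc[lig]
            out[lig] = {"system_Emax": float(row.system_Emax_fold_over_basal),
                        "tau": float(row.tau),
                        "pKA": float(row.pKA_neg_log10_M)}
        out["JR7"] = {"responds": False}
        return out

    return {
        "seed": seed,
        "reference": "carbachol",
        "standards": list(STANDARDS),
        "simulate": {
            "constructs": [
                {"receptor": "M2", "variant": "fused",
                 "functional": truths("M2"), "system_Emax": 30.7,
                 "binding": {"carbachol": {"pKI_low": 4.62},
                             "oxotremorine": {"pKI_low": 5.70}},
                 "saturation": {"pKD": 9.0, "BMAX_pmol_mg": 2.0}},
                {"receptor": "M4", "variant": "fused",
                 "functional": truths("M4"), "system_Emax": 27.1,
                 "binding": {"carbachol": {"pKI_low": 4.61},
                             "oxotremorine": {"pKI_low": 5.86}},
                 "saturation": {"pKD": 9.0, "BMAX_pmol_mg": 2.0}},
            ],
        },
    }


def simulate_study(study: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format table and ground-truth sidecar for a study."""
    cfg = SimulationConfig(rng_seed=int(study["seed"]),
                           n_experiments=int(study.get("n_experiments", 3)))
    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for spec in study["simulate"]["constructs"]:
        receptor, variant = spec["receptor"], spec["variant"]
        construct = ReceptorConstruct(receptor, variant, "IPx")
        for lig, t in spec.get("functional", {}).items():
            truth = FunctionalTruth(**t) if t.get("responds", True) \
                else FunctionalTruth(responds=False)
            for e in range(cfg.n_experiments):
                series, rec = simulate_functional(cfg, lig, truth, construct,
                                                  experiment=e)
                frames.append(series_to_frame(series, "fold_over_basal",
                                              receptor=receptor))
                truth_rows.append({"receptor": receptor, "variant": variant,
                                   "kind": "functional", "ligand": lig,
                                   "experiment": e + 1, **{k: v for k, v in
                                                           rec.items()
                                                           if np.isscalar(v) or v is None}})
        for lig, t in spec.get("binding", {}).items():
            truth = CompetitionTruth(**t)
            for e in range(cfg.n_experiments):
                series, rec = simulate_competition(cfg, lig, truth, construct,
                                                   experiment=e)
                frames.append(series_to_frame(series, "pct_control",
                                              receptor=receptor,
                                              pathway="binding"))
                truth_rows.append({"receptor": receptor, "variant": variant,
                                   "kind": "competition", "ligand": lig,
                                   "experiment": e + 1, **{k: v for k, v in
                                                           rec.items()
                                                           if np.isscalar(v) or v is None}})
        if "saturation" in spec:
            truth = SaturationTruth(**spec["saturation"])
            for e in range(cfg.n_experiments):
                series, rec = simulate_saturation(cfg, truth, experiment=e)
                frames.append(saturation_to_frame(series, receptor=receptor,
                                                  variant=variant))
                truth_rows.append({"receptor": receptor, "variant": variant,
                                   "kind": "saturation", "experiment": e + 1,
                                   "pKD": rec["pKD"],
                                   "BMAX_pmol_mg": rec["BMAX_pmol_mg"]})
    long_df = pd.concat(frames, ignore_index=True)
    return long_df, pd.DataFrame(truth_rows)


def fit_binding_table(table: LongTable, radioligand_conc: float = 1e-9,
                      radioligand_pKD: float = 9.0) -> pd.DataFrame:
    """Fit all binding series and summarise per (receptor, variant, ligand)."""
    rows = []
    for series in table.saturation:
        fit = fit_saturation(series)
        rows.append({"kind": "saturation", "experiment": series.experiment_id,
                     "pKD_neg_log10_M": fit.pKD, "pKD_se": fit.pKD_se,
                     "BMAX_pmol_per_mg": fit.BMAX, "BMAX_se": fit.BMAX_se})
    by_key: dict[tuple, list] = {}
    for series in table.competition:
        key = (series.construct.subtype.value, series.construct.variant.value,
               series.ligand.name)
        fit = fit_competition(series, radioligand_conc, radioligand_pKD)
        by_key.setdefault(key, []).append(fit)
        rows.append({"kind": "competition", "receptor": key[0],
                     "variant": key[1], "ligand": key[2],
                     "experiment": series.experiment_id, "model": fit.model,
                     "pKI_low_neg_log10_M": fit.pKI_low,
                     "pKI_high_neg_log10_M": fit.pKI_high,
                     "f_low_pct": fit.f_low, "F": fit.F_statistic,
                     "p_value": fit.p_value})
    for key, fits in by_key.items():
        summary = summarize_competition_fits(fits)
        rows.append({"kind": "competition_summary", "receptor": key[0],
                     "variant": key[1], "ligand": key[2],
                     "n_experiments": summary["n_experiments"],
                     "pKI_low_neg_log10_M": summary["pKI_low_mean"],
                     "pKI_low_sd": summary["pKI_low_sd"]})
    return pd.DataFrame(rows)


def fit_functional_table(table: LongTable, standards=STANDARDS,
                         baseline: str = "rebased",
                         system_emax=None) -> pd.DataFrame:
    """Hill + two-step operational fits for every functional series.

    Step 1 pools the internal-standard curves of each (receptor, variant,
    pathway) across experiments into one global shared-E_MAX profile fit;
    step 2 fits every individual experiment with E_MAX fixed.  When the study
    states the system ceiling (``system_emax``: scalar, or dict keyed by
    (receptor, variant, pathway)), step 2 uses it directly — the shared-E_MAX
    likelihood is flat above the largest apparent maximum for unit-slope
    curves, so the data alone only bound the ceiling from below.
    """
    groups: dict[tuple, list] = {}
    for s in table.functional:
        key = (s.construct.subtype.value, s.construct.variant.value,
               s.construct.pathway.value)
        groups.setdefault(key, []).append(s)
    rows = []
    for key, series_list in sorted(groups.items()):
        fixed = system_emax.get(key) if isinstance(system_emax, dict) \
            else system_emax
        if fixed is not None:
            emax_value, emax_se = float(fixed), math.nan
        else:
            std = [s for s in series_list if s.ligand.name in standards
                   and flat_test(s).coupled]
            emax_fit = fit_system_emax(std, baseline=baseline)
            emax_value, emax_se = emax_fit.system_Emax, emax_fit.system_Emax_se
        per_ligand: dict[str, list] = {}
        for s in sorted(series_list, key=lambda s: (s.ligand.name,
                                                    s.experiment_id)):
            hill = fit_hill(s)
            op = fit_operational(s, emax_value, baseline=baseline)
            per_ligand.setdefault(s.ligand.name, []).append(op)
            rows.append({
                "receptor": key[0], "variant": key[1], "pathway": key[2],
                "ligand": s.ligand.name, "level": "experiment",
                "experiment": s.experiment_id,
                "pEC50_neg_log10_M": hill.pEC50, "EmaxPrime_fold": hill.EmaxPrime,
                "nH": hill.nH, "no_response": hill.no_response,
                "system_Emax_fold": emax_value,
                "system_Emax_se": emax_se,
                "tau": op.tau, "pKA_neg_log10_M": op.pKA,
            })
        for lig, ops in per_ligand.items():
            taus = np.array([o.tau for o in ops])
            pkas = np.array([o.pKA if o.pKA is not None else np.nan
                             for o in ops])
            rows.append({
                "receptor": key[0], "variant": key[1], "pathway": key[2],
                "ligand": lig, "level": "summary", "n_experiments": len(ops),
                "system_Emax_fold": emax_value,
                "tau": float(taus.mean()),
                "tau_sd": float(taus.std(ddof=1)) if len(ops) > 1 else math.nan,
                "pKA_neg_log10_M": (float(np.nanmean(pkas))
                                    if np.isfinite(pkas).any() else None),
                "pKA_sd": (float(np.nanstd(pkas, ddof=1))
                           if np.isfinite(pkas).sum() > 1 else math.nan),
            })
    return pd.DataFrame(rows)


def bias_from_params(params: pd.DataFrame, reference: str = "carbachol",
                     group_col: str = "receptor") -> dict:
    """Table-mode bias: RA_i, rankings and pairwise bias factors.

    ``params`` needs columns ``group_col``, ``ligand`` and either
    (``tau``, ``pKA_neg_log10_M``) or (``pEC50_neg_log10_M``,
    ``EmaxPrime_fold``); no raw curves are required.
    """
    has_op = "tau" in params.columns and "pKA_neg_log10_M" in params.columns
    fits_by_group: dict[str, dict] = {}
    for g, sub in params.groupby(group_col):
        fits = {}
        for _, row in sub.iterrows():
            if has_op and pd.notna(row["tau"]):
                pka = row["pKA_neg_log10_M"]
                fits[row["ligand"]] = OperationalFit(
                    system_Emax=float(row.get("system_Emax_fold", np.nan))
                    if "system_Emax_fold" in row else math.nan,
                    tau=float(row["tau"]),
                    pKA=None if pd.isna(pka) else float(pka),
                    tau_se=float(row["tau_sd"]) if "tau_sd" in row
                    and pd.notna(row["tau_sd"]) else math.nan,
                    pKA_se=float(row["pKA_sd"]) if "pKA_sd" in row
                    and pd.notna(row["pKA_sd"]) else math.nan)
            else:
                fits[row["ligand"]] = HillFit(
                    pEC50=float(row["pEC50_neg_log10_M"]),
                    EmaxPrime=float(row["EmaxPrime_fold"]), nH=1.0)
        fits_by_group[str(g)] = fits

    rai_frames = []
    for g, fits in fits_by_group.items():
        df = compute_RAi_table(fits, reference)
        df.insert(0, group_col, g)
        rai_frames.append(df)
    rai = pd.concat(rai_frames, ignore_index=True)

    ligands = sorted({l for fits in fits_by_group.values() for l in fits})
    factor_rows = []
    group_names = sorted(fits_by_group)
    for lig in ligands:
        if lig == reference:
            continue
        for i, a in enumerate(group_names):
            for b in group_names[i + 1:]:
                if lig not in fits_by_group[a] or lig not in fits_by_group[b]:
                    continue
                r = compute_bias_factor(fits_by_group[a], fits_by_group[b],
                                        lig, reference, a, b)
                factor_rows.append({
                    "ligand": lig, "construct_a": a, "construct_b": b,
                    "ddlog_tau_over_KA": r.ddlog_tau_over_KA,
                    "bias_factor": r.bias_factor})
    factors = pd.DataFrame(factor_rows)

    # rankings: prefer across-experiment RA_i summary statistics when the
    # input table carries them (within-experiment normalisation gives much
    # tighter SDs than delta-method propagation from tau/pKA SDs)
    if "RAi" in params.columns and "RAi_sd" in params.columns:
        rank_src = params.rename(columns={group_col: "_g"})[
            ["_g", "ligand", "RAi", "RAi_sd"]]
    else:
        rank_src = rai.rename(columns={group_col: "_g"})[
            ["_g", "ligand", "RAi", "RAi_sd"]]
    rankings = {}
    for lig in ligands:
        sub = rank_src[rank_src.ligand == lig].dropna(subset=["RAi"])
        vals = dict(zip(sub["_g"].astype(str), sub["RAi"].astype(float)))
        sds = dict(zip(sub["_g"].astype(str),
                       sub["RAi_sd"].fillna(0.0).astype(float)))
        if len(vals) >= 2 and any(v > 0 for v in vals.values()):
            rankings[lig] = format_ranking(rank_constructs(vals, sds))
    return {"rai": rai, "bias_factors": factors, "rankings": rankings}


def run_pipeline(study: dict, output_dir) -> dict:
    """Execute all stages of a study; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"opbias {__version__} pipeline run",
                 f"seed: {study.get('seed')}",
                 f"reference ligand: {study.get('reference', 'carbachol')}",
                 f"internal standards: {study.get('standards', list(STANDARDS))}"]
    paths = {}

    if "simulate" in study:
        long_df, truth = simulate_study(study)
        paths["data"] = out / "data_long.csv"
        long_df.to_csv(paths["data"], index=False)
        paths["truth"] = out / "ground_truth.csv"
        truth.to_csv(paths["truth"], index=False)
        log_lines.append(f"simulated {len(long_df)} wells")
    elif "data" in study:
        paths["data"] = Path(study["data"])
    else:
        raise ValueError("study config must name input data or a simulation spec")

    table = read_long_csv(paths["data"])
    log_lines.append(f"series: {len(table.functional)} functional, "
                     f"{len(table.competition)} competition, "
                     f"{len(table.saturation)} saturation")

    try:
        if table.saturation or table.competition:
            binding_df = fit_binding_table(table)
            paths["binding"] = out / "binding_params.csv"
            binding_df.to_csv(paths["binding"], index=False)
            log_lines.append("binding fits: ok")
        emax_map = {}
        for spec in study.get("simulate", {}).get("constructs", []):
            if "system_Emax" in spec:
                emax_map[(spec["receptor"], spec["variant"], "IPx")] = \
                    float(spec["system_Emax"])
        for key, val in study.get("system_Emax", {}).items() \
                if isinstance(study.get("system_Emax"), dict) else []:
            emax_map[tuple(key.split(":"))] = float(val)
        functional_df = fit_functional_table(
            table, standards=study.get("standards", STANDARDS),
            system_emax=emax_map or None)
        paths["functional"] = out / "functional_params.csv"
        functional_df.to_csv(paths["functional"], index=False)
        log_lines.append("functional fits: ok")

        summary = functional_df[functional_df.level == "summary"]
        bias = bias_from_params(summary,
                                reference=study.get("reference", "carbachol"))
        paths["bias"] = out / "bias_report.csv"
        bias["rai"].to_csv(paths["bias"], index=False)
        paths["bias_factors"] = out / "bias_factors.csv"
        bias["bias_factors"].to_csv(paths["bias_factors"], index=False)
        log_lines.append("bias: ok; rankings: "
                         + json.dumps(bias["rankings"], sort_keys=True))

        rai_by_ligand = {}
        for lig, sub in bias["rai"].groupby("ligand"):
            vals = dict(zip(sub["receptor"], sub["RAi"]))
            if any(v > 0 for v in vals.values()):
                rai_by_ligand[lig] = vals
        from .plots import polar_rai_plot
        paths["plot"] = out / "rai_polar.svg"
        polar_rai_plot(rai_by_ligand, outfile=paths["plot"])
    except Exception as exc:  # pragma: no cover - abort path
        log_lines.append(f"ABORTED: {type(exc).__name__}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise

    paths["log"] = out / "run_log.txt"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
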