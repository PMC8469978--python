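"""Long-format CSV ingest and export with unit normalisation.

The canonical exchange format is one row per well:

    experiment_id, receptor, variant, pathway, ligand,
    concentration, conc_unit, replicate, response, response_unit

Concentrations are canonicalised to molar at ingest (M, mM, uM/µM, nM, pM
accepted).  ``response_unit`` distinguishes the data kinds:
``fold_over_basal`` (functional), ``pct_control`` (competition binding) and
the paired ``dpm_total`` / ``dpm_nonspecific`` rows of a saturation plate.
Validation is row-level: offending rows are itemised with line numbers and
the whole file is rejected if any row fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    ConcResponseSeries,
    Ligand,
    ReceptorConstruct,
    SaturationSeries,
)

__all__ = ["UNIT_TO_MOLAR", "LongTable", "read_long_csv", "write_long_csv",
           "series_to_frame", "ValidationError"]

UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
                 "pM": 1e-12}

COLUMNS = ["experiment_id", "receptor", "variant", "pathway", "ligand",
           "concentration", "conc_unit", "replicate", "response",
           "response_unit"]

RESPONSE_UNITS = {"fold_over_basal", "pct_control", "dpm_total",
                  "dpm_nonspecific", "dpm"}


class ValidationError(ValueError):
    """Raised with an itemised, line-numbered list of rejected rows."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "input validation failed:\n" + "\n".join(problems))


@dataclass
class LongTable:
    """Validated long-format data grouped into typed series."""

    functional: list[ConcResponseSeries] = field(default_factory=list)
    competition: list[ConcResponseSeries] = field(default_factory=list)
    saturation: list[SaturationSeries] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.functional) + len(self.competition) + len(self.saturation)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    problems: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {missing}"])
    if df.empty:
        raise ValidationError(["no data rows"])
    conc_m = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        unit = str(row.conc_unit)
        if unit not in UNIT_TO_MOLAR:
            problems.append(f"line {line}: unknown concentration unit {unit!r}")
            conc_m[i] = np.nan
            continue
        c = float(row.concentration)
        if c < 0:
            problems.append(f"line {line}: negative concentration {c}")
        if str(row.response_unit) not in RESPONSE_UNITS:
            problems.append(
                f"line {line}: unknown response unit {row.response_unit!r}")
        conc_m[i] = c * UNIT_TO_MOLAR[unit]
    out = df.copy()
    out["conc_M"] = conc_m
    key_cols = ["experiment_id", "receptor", "variant", "pathway", "ligand",
                "response_unit", "conc_M", "replicate"]
    dup = out.duplicated(subset=key_cols, keep=False)
    if dup.any():
        for idx in out.index[dup]:
            problems.append(
                f"line {idx + 2}: duplicate (series, concentration, replicate) key")
    if problems:
        raise ValidationError(problems)
    return out


def _pivot_responses(g: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Build (concentrations, response matrix) from long rows of one series."""
    wide = g.pivot_table(index="conc_M", columns="replicate", values="response",
                         aggfunc="first")
    wide = wide.sort_index()
    return wide.index.to_numpy(), wide.to_numpy()


def read_long_csv(path) -> LongTable:
    """Read and validate a long-format CSV into typed series collections."""
    df = pd.read_csv(path)
    df = _validate(df)
    table = LongTable()
    group_cols = ["experiment_id", "receptor", "variant", "pathway", "ligand"]
    for key, g in df.groupby(group_cols, sort=True):
        exp, receptor, variant, pathway, ligand = key
        units = set(g["response_unit"])
        construct_pathway = pathway if pathway in ("IPx", "cAMP") else "IPx"
        construct = ReceptorConstruct(receptor, variant, construct_pathway)
        if units <= {"fold_over_basal"} or units <= {"pct_control"}:
            conc, resp = _pivot_responses(g)
            pos = conc > 0
            series = ConcResponseSeries(
                construct=construct, ligand=Ligand(str(ligand)),
                concentrations=conc[pos], responses=resp[pos],
                experiment_id=str(exp),
            )
            if units == {"pct_control"}:
                table.competition.append(series)
            else:
                table.functional.append(series)
        elif units == {"dpm_total", "dpm_nonspecific"}:
            tot = g[g.response_unit == "dpm_total"]
            ns = g[g.response_unit == "dpm_nonspecific"]
            conc_t, resp_t = _pivot_responses(tot)
            conc_n, resp_n = _pivot_responses(ns)
            if conc_t.size != conc_n.size or not np.allclose(conc_t, conc_n):
                raise ValidationError(
                    [f"saturation series {key}: total and nonspecific rows "
                     "do not share a concentration grid"])
            table.saturation.append(SaturationSeries(
                added_conc_pM=conc_t * 1e12, total_dpm=resp_t,
                nonspecific_dpm=resp_n, experiment_id=str(exp)))
        else:
            raise ValidationError(
                [f"series {key}: inconsistent response units {sorted(units)}"])
    return table


def series_to_frame(series: ConcResponseSeries, response_unit: str,
                    receptor: str | None = None,
                    pathway: str | None = None) -> pd.DataFrame:
    rows = []
    c = series.construct
    for i, conc in enumerate(series.concentrations):
        for r in range(series.n_replicates):
            val = series.responses[i, r]
            if np.isnan(val):
                continue
            rows.append({
                "experiment_id": series.experiment_id,
                "receptor": receptor or c.subtype.value,
                "variant": c.variant.value,
                "pathway": pathway or c.pathway.value,
                "ligand": series.ligand.name,
                "concentration": conc, "conc_unit": "M",
                "replicate": r + 1, "response": val,
                "response_unit": response_unit,
            })
    return pd.DataFrame(rows, columns=COLUMNS)


def saturation_to_frame(series: SaturationSeries, receptor: str = "M2",
                        variant: str = "fused") -> pd.DataFrame:
    rows = []
    for unit, mat in (("dpm_total", series.total_dpm),
                      ("dpm_nonspecific", series.nonspecific_dpm)):
        for i, conc_pm in enumerate(series.added_conc_pM):
            for r in range(mat.shape[1]):
                rows.append({
                    "experiment_id": series.experiment_id,
                    "receptor": receptor, "variant": variant,
                    "pathway": "binding", "ligand": "[3H]NMS",
                    "concentration": conc_pm, "conc_unit": "pM",
                    "replicate": r + 1, "response": mat[i, r],
                    "response_unit": unit,
                })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_long_csv(frames: list[pd.DataFrame], path) -> None:
    """Concatenate long-format frames and write a canonical CSV."""
    df = pd.concat(frames, ignore_index=True)[COLUMNS]
    df.to_csv(path, index=False)
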