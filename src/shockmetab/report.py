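"""Diagnostics and VIP report tables, Welch's t, and heatmap-ready matrices."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import GROUPS, MetabolomicsDataset
from .plsda import VIPTable, select_vip
from .validation import CVDiagnostics, PermutationResult

DIAGNOSTIC_COLUMNS = ["contrast", "compartment", "R2", "NMC", "sd", "Accuracy", "p"]


def welch_t(group_a: Sequence[float], group_b: Sequence[float]
            ) -> tuple[float, float, float]:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df).

    Returns ``(t, df, p)``; used for lab-value comparisons such as serum
    urea, which sits outside the multivariate panel.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def build_diagnostics(entries: Sequence[tuple[str, str, CVDiagnostics,
                                              PermutationResult | None]]
                      ) -> pd.DataFrame:
    """Model-diagnostics table: one row per analyzed (contrast, compartment).

    Columns: R2 (R2Y of the final full-data model), NMC mean and sd over the
    outer repeats, pooled classification accuracy in percent, and the
    permutation p-value.
    """
    rows = []
    for contrast, compartment, diag, perm in entries:
        rows.append({
            "contrast": contrast,
            "compartment": compartment,
            "R2": diag.r2y,
            "NMC": diag.nmc_mean,
            "sd": diag.nmc_sd,
            "Accuracy": diag.classification_accuracy,
            "p": perm.p_value if perm is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=DIAGNOSTIC_COLUMNS)


def write_diagnostics(table: pd.DataFrame, csv_path: str | Path,
                      json_path: str | Path | None = None) -> None:
    table.to_csv(Path(csv_path), index=False, float_format="%.6g")
    if json_path is not None:
        records = table.to_dict(orient="records")
        Path(json_path).write_text(json.dumps(records, indent=1, sort_keys=True,
                                              allow_nan=True) + "\n")


def read_diagnostics_json(path: str | Path) -> pd.DataFrame:
    records = json.loads(Path(path).read_text())
    return pd.DataFrame(records, columns=DIAGNOSTIC_COLUMNS)


@dataclass
class VIPReport:
    """VIP metabolites with per-group means for one contrast x compartment.

    ``table`` columns: metabolite, vip, rank, selected, mean_CPF, mean_FS —
    means on the analysis scale of the contrast (baseline level or interval
    change) in the compartment's units.  ``selected`` mirrors the VIP >= 1.0,
    top-10 rule, i.e. the bold entries of a per-contrast metabolite table.
    """

    contrast: str
    compartment: str
    units: str
    table: pd.DataFrame

    def selected_metabolites(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return sel.sort_values("rank")["metabolite"].tolist()


def build_vip_report(contrast: str, vip: VIPTable,
                     analysis_ds: MetabolomicsDataset) -> VIPReport:
    """Attach per-group analysis-scale means to a VIP table."""
    frame = vip.to_frame()
    meta = analysis_ds.sample_meta
    name_to_col = {m: j for j, m in enumerate(analysis_ds.metabolite_names)}
    for group in GROUPS:
        rows = (meta["group"] == group).to_numpy()
        means = []
        for m in frame["metabolite"]:
            j = name_to_col.get(m)
            means.append(np.nan if j is None
                         else float(np.nanmean(analysis_ds.values[rows, j]))
                         if rows.any() else np.nan)
        frame[f"mean_{group}"] = means
    return VIPReport(contrast=contrast, compartment=analysis_ds.compartment,
                     units=analysis_ds.units, table=frame)


def heatmap_matrix(reports: Sequence[VIPReport]) -> pd.DataFrame:
    """Min-max scaled group-mean matrix over the selected VIP metabolites.

    Rows are (compartment, metabolite); columns are (contrast, group).  Each
    row is scaled to [0, 1] across its observed cells so compartments with
    very different units share one color scale; constant rows map to 0.5.
    """
    cells: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    for rep in reports:
        sel = rep.table[rep.table["selected"]]
        for _, row in sel.iterrows():
            key = (rep.compartment, row["metabolite"])
            cells.setdefault(key, {})
            for group in GROUPS:
                cells[key][(rep.contrast, group)] = row[f"mean_{group}"]
    if not cells:
        return pd.DataFrame()
    frame = pd.DataFrame.from_dict(cells, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index,
                                            names=["compartment", "metabolite"])
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["contrast", "group"])
    frame = frame.sort_index(axis=0).sort_index(axis=1)

    def _scale_row(row: pd.Series) -> pd.Series:
        lo, hi = row.min(), row.max()
        if not np.isfinite(hi - lo) or hi == lo:
            return pd.Series(np.where(row.notna(), 0.5, np.nan), index=row.index)
        return (row - lo) / (hi - lo)

    return frame.apply(_scale_row, axis=1)
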