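"""Urine flow normalization, log-offset transform, interval differencing, autoscaling.

Order of operations mirrors the analysis pipeline: urine concentrations are
multiplied by urine output (flow normalization to nmol/h/kg) and
log10-transformed with a +0.1 offset *before* any differencing or scaling;
liver/muscle/serum enter differencing on the raw concentration scale.  Every
contrast matrix is autoscaled (per-column mean 0, sample sd 1) before PCA or
PLS-DA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (INTERVAL_PAIRS, NORMALIZED_URINE_UNITS, TIMEPOINTS,
                      ContrastSpec, DataValidationError, MetabolomicsDataset)

log = logging.getLogger(__name__)


class EmptyContrastError(ValueError):
    """No animal has observations at both endpoints of an interval."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Transform parameters.

    ``unit_factor_urine`` converts mM x cc/hr/kg to nmol/h/kg
    (mM = umol/mL, so umol/h/kg x 1000 = nmol/h/kg).  ``log_offset`` is
    added before the base-10 logarithm so exact zeros map to -1.
    ``urine_difference_scale`` selects whether urine interval differences
    are taken on the log scale (default) or the normalized abundance scale.
    """

    log_base: float = 10.0
    log_offset: float = 0.1
    unit_factor_urine: float = 1000.0
    scaling: str = "autoscale"
    urine_difference_scale: str = "log"

    def __post_init__(self) -> None:
        if self.log_offset <= 0:
            raise DataValidationError("log_offset must be > 0")
        if self.unit_factor_urine <= 0:
            raise DataValidationError("unit_factor_urine must be > 0")
        if self.scaling != "autoscale":
            raise DataValidationError("only autoscale scaling is supported")
        if self.urine_difference_scale not in ("log", "normalized"):
            raise DataValidationError("urine_difference_scale must be 'log' or 'normalized'")


# ---------------------------------------------------------------------------
# elementwise transforms

def normalize_urine(conc_mM: np.ndarray, output_cc_hr_kg: np.ndarray | float,
                    unit_factor: float = 1000.0) -> np.ndarray:
    """Flow-normalize urine concentrations: abundance = conc x flow x factor.

    With the default factor, mM concentrations and cc/hr/kg flow yield
    abundances in nmol/h/kg.  Zero concentration stays zero for any flow;
    zero flow (an anuric sample) zeroes every abundance.
    """
    conc = np.asarray(conc_mM, dtype=float)
    flow = np.asarray(output_cc_hr_kg, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(conc < 0):
            raise DataValidationError("urine concentrations must be >= 0")
        if np.any(flow < 0):
            raise DataValidationError("urine output must be >= 0")
    if flow.ndim == 1 and conc.ndim == 2:
        flow = flow[:, None]
    return conc * flow * unit_factor


def log_transform(abundance: np.ndarray, offset: float = 0.1,
                  base: float = 10.0) -> np.ndarray:
    """log_base(abundance + offset); with the defaults, 0 maps to exactly -1."""
    x = np.asarray(abundance, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(x < 0):
            raise DataValidationError("abundances must be >= 0 before log transform")
    return np.log(x + offset) / math.log(base)


def normalize_urine_dataset(ds: MetabolomicsDataset,
                            cfg: PreprocessConfig = PreprocessConfig()
                            ) -> MetabolomicsDataset:
    """Apply flow normalization per urine sample using the metadata flow column."""
    if ds.compartment != "urine":
        raise DataValidationError("flow normalization applies to urine only")
    if "urine_output" not in ds.sample_meta.columns:
        raise DataValidationError("urine dataset lacks the urine_output column")
    flow = ds.sample_meta["urine_output"].to_numpy(dtype=float)
    bad = np.isnan(flow)
    if bad.any():
        who = ds.sample_meta.loc[bad, ["animal_id", "timepoint"]].iloc[0]
        raise DataValidationError(
            f"missing urine output for sample ({who.animal_id}, {who.timepoint})")
    values = normalize_urine(ds.values, flow, cfg.unit_factor_urine)
    return ds.with_values(values, units=NORMALIZED_URINE_UNITS)


def log_transform_dataset(ds: MetabolomicsDataset,
                          cfg: PreprocessConfig = PreprocessConfig()
                          ) -> MetabolomicsDataset:
    values = log_transform(ds.values, cfg.log_offset, cfg.log_base)
    # transformed values may dip below zero; mark the dataset sign-free
    return MetabolomicsDataset(values=values, metabolite_names=list(ds.metabolite_names),
                               sample_meta=ds.sample_meta.copy(),
                               units=f"log10({ds.units} + {cfg.log_offset:g})",
                               kind="transformed")


# ---------------------------------------------------------------------------
# differencing

def compute_interval(ds: MetabolomicsDataset, later: str, earlier: str
                     ) -> MetabolomicsDataset:
    """Per-animal later-minus-earlier differences for a consecutive interval.

    One output row per animal observed at BOTH timepoints; animals missing
    either endpoint are excluded for this contrast only (logged).  The
    degenerate pair (t, t) is accepted and yields all-zero rows, which is
    useful as a self-consistency check.
    """
    if later != earlier and (later, earlier) not in INTERVAL_PAIRS:
        raise DataValidationError(
            f"({later}, {earlier}) is not a consecutive study interval")
    meta = ds.sample_meta
    at_later = meta["timepoint"] == later
    at_earlier = meta["timepoint"] == earlier
    later_row = {a: i for i, a in zip(np.flatnonzero(at_later),
                                      meta.loc[at_later, "animal_id"])}
    earlier_row = {a: i for i, a in zip(np.flatnonzero(at_earlier),
                                        meta.loc[at_earlier, "animal_id"])}
    common = [a for a in later_row if a in earlier_row]
    excluded = sorted((set(later_row) | set(earlier_row)) - set(common))
    if excluded:
        log.info("interval %s-%s: excluded %d animal(s) missing an endpoint: %s",
                 later, earlier, len(excluded), ", ".join(excluded))
    if not common:
        raise EmptyContrastError(
            f"no animal observed at both {later} and {earlier}")
    li = [later_row[a] for a in common]
    ei = [earlier_row[a] for a in common]
    diff = ds.values[li] - ds.values[ei]
    meta_out = meta.iloc[li][["animal_id", "group", "compartment"]].copy()
    meta_out["timepoint"] = f"{later}-{earlier}"
    return MetabolomicsDataset(values=diff, metabolite_names=list(ds.metabolite_names),
                               sample_meta=meta_out, units=ds.units,
                               kind="difference")


# ---------------------------------------------------------------------------
# autoscaling

@dataclass
class ScaledMatrix:
    """Column-autoscaled matrix with its scaling parameters.

    ``kept`` indexes the retained columns of the input; zero-variance
    columns are dropped (autoscaling is undefined for them and PLS weights
    would be 0/0) and listed in ``dropped``.
    """

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray
    dropped: list[str]
    names: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def autoscale(X: np.ndarray, names: Sequence[str] | None = None) -> ScaledMatrix:
    """Center each column to mean 0 and scale to unit sample sd (n-1 denominator)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataValidationError("autoscale expects a 2-D matrix")
    n, p = X.shape
    if n < 2:
        raise DataValidationError("autoscale requires at least 2 rows")
    if np.isnan(X).any():
        raise DataValidationError(
            "missing values must be resolved (rows excluded) before scaling")
    if names is None:
        names = [str(j) for j in range(p)]
    names = list(names)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0.0
    kept = np.flatnonzero(keep)
    dropped = [names[j] for j in np.flatnonzero(~keep)]
    if dropped:
        log.info("autoscale: dropped %d zero-variance column(s): %s",
                 len(dropped), ", ".join(dropped))
    scaled = (X[:, kept] - means[kept]) / sds[kept]
    return ScaledMatrix(values=scaled, means=means[kept], sds=sds[kept],
                        kept=kept, dropped=dropped,
                        names=[names[j] for j in kept])


# ---------------------------------------------------------------------------
# contrast assembly

def prepare_contrast(datasets: Mapping[str, MetabolomicsDataset],
                     contrast: ContrastSpec,
                     cfg: PreprocessConfig = PreprocessConfig()
                     ) -> MetabolomicsDataset:
    """Assemble the analysis-scale dataset for one compartment x contrast.

    Urine is flow-normalized and log-transformed first; tissue and serum
    stay on the concentration scale.  Timepoint contrasts subset the rows at
    that timepoint; interval contrasts difference per animal.  Rows with any
    missing value are excluded (logged) so the matrix is complete for
    scaling.
    """
    ds = datasets[contrast.compartment]
    if contrast.compartment == "urine":
        ds = normalize_urine_dataset(ds, cfg)
        if contrast.kind == "interval" and cfg.urine_difference_scale == "normalized":
            pass  # difference the normalized abundances, log applied downstream never
        else:
            ds = log_transform_dataset(ds, cfg)
    if contrast.kind == "timepoint":
        mask = (ds.sample_meta["timepoint"] == contrast.timepoint).to_numpy()
        if not mask.any():
            raise EmptyContrastError(f"no samples at timepoint {contrast.timepoint}")
        out = ds.subset(mask)
    else:
        out = compute_interval(ds, contrast.later, contrast.earlier)
    complete = ~np.isnan(out.values).any(axis=1)
    if not complete.all():
        dropped = out.sample_meta.loc[~complete, "animal_id"].tolist()
        log.info("contrast %s/%s: excluded %d sample(s) with missing values: %s",
                 contrast.compartment, contrast.label, len(dropped),
                 ", ".join(dropped))
        out = out.subset(complete)
    return out
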