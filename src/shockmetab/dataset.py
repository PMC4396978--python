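"""Dataset model and delimited-text interchange for metabolite concentration panels.

A :class:`MetabolomicsDataset` holds one compartment's samples-by-metabolites
matrix together with per-sample metadata (animal, group, timepoint and, for
urine, the urine output used for flow normalization).  The on-disk
interchange format is a long/tidy delimited table with one row per
(sample, metabolite) cell, which tolerates ragged panels across compartments;
a wide writer is provided for report-style matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("CPF", "FS")
COMPARTMENTS = ("liver", "muscle", "serum", "urine")
TIMEPOINTS = ("B", "S45", "FR2", "FR8", "FR20", "PR48")
#: consecutive study intervals analyzed as per-animal differences
INTERVAL_PAIRS = (("S45", "B"), ("FR2", "S45"), ("FR8", "FR2"), ("FR20", "FR8"))

RAW_UNITS = {
    "liver": "mM/g lyophilized tissue",
    "muscle": "mM/g lyophilized tissue",
    "serum": "mM",
    "urine": "mM",
}
NORMALIZED_URINE_UNITS = "nmol/h/kg"

LONG_COLUMNS = ("animal_id", "group", "compartment", "timepoint",
                "urine_output", "metabolite", "value")
_META_REQUIRED = ("animal_id", "group", "compartment", "timepoint")


class SchemaError(ValueError):
    """A required metadata column is absent or malformed."""


class IntegrityError(ValueError):
    """Duplicate or mutually inconsistent sample rows."""


class DataValidationError(ValueError):
    """Values violate the dataset invariants (negative, non-finite, ...)."""


@dataclass(frozen=True)
class ContrastSpec:
    """A single analysis contrast: one timepoint or one consecutive interval.

    ``kind`` is ``"timepoint"`` when only ``timepoint`` is set and
    ``"interval"`` when ``later``/``earlier`` are set.  Interval pairs are
    restricted to the consecutive study pairs (S45-B, FR2-S45, FR8-FR2,
    FR20-FR8).
    """

    compartment: str
    timepoint: str | None = None
    later: str | None = None
    earlier: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise SchemaError(f"unknown compartment {self.compartment!r}")
        if self.timepoint is not None:
            if self.later is not None or self.earlier is not None:
                raise SchemaError("give either a timepoint or an interval pair, not both")
            if self.timepoint not in TIMEPOINTS:
                raise SchemaError(f"unknown timepoint {self.timepoint!r}")
        else:
            if (self.later, self.earlier) not in INTERVAL_PAIRS:
                raise SchemaError(
                    f"({self.later}, {self.earlier}) is not a consecutive study interval; "
                    f"allowed: {INTERVAL_PAIRS}")

    @property
    def kind(self) -> str:
        return "timepoint" if self.timepoint is not None else "interval"

    @property
    def label(self) -> str:
        if self.kind == "timepoint":
            return self.timepoint  # type: ignore[return-value]
        return f"{self.later}-{self.earlier}"

    @classmethod
    def from_label(cls, label: str, compartment: str) -> "ContrastSpec":
        """Parse ``"B"`` or ``"S45-B"`` style labels."""
        if "-" in label:
            later, earlier = label.split("-", 1)
            return cls(compartment=compartment, later=later, earlier=earlier)
        return cls(compartment=compartment, timepoint=label)


@dataclass
class MetabolomicsDataset:
    """One compartment's concentration matrix plus per-sample metadata.

    Parameters
    ----------
    values
        ``(n_samples, n_metabolites)`` float array; ``NaN`` marks a missing
        measurement (never encoded as zero — zeros are data).
    metabolite_names
        Column labels, matched case-sensitively.
    sample_meta
        One row per sample with columns ``animal_id``, ``group``,
        ``compartment``, ``timepoint`` and optionally ``urine_output``
        (cc/hr/kg, required on urine rows before normalization).
    units
        Unit string for the value matrix.
    kind
        ``"raw"`` for concentrations (non-negative) or ``"difference"`` for
        per-animal interval differences (sign-free).
    """

    values: np.ndarray
    metabolite_names: list[str]
    sample_meta: pd.DataFrame
    units: str
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D samples x metabolites array")
        self.metabolite_names = [str(m) for m in self.metabolite_names]
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.metabolite_names) != p:
            raise SchemaError(
                f"{p} value columns but {len(self.metabolite_names)} metabolite names")
        if len(set(self.metabolite_names)) != p:
            raise IntegrityError("duplicate metabolite names")
        if len(self.sample_meta) != n:
            raise SchemaError(f"{n} value rows but {len(self.sample_meta)} metadata rows")
        missing = [c for c in _META_REQUIRED if c not in self.sample_meta.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        if n:
            comps = self.sample_meta["compartment"].unique()
            if len(comps) > 1:
                raise IntegrityError(f"dataset mixes compartments {sorted(comps)}")
            if comps[0] not in COMPARTMENTS:
                raise SchemaError(f"unknown compartment {comps[0]!r}")
            bad_groups = set(self.sample_meta["group"]) - set(GROUPS)
            if bad_groups:
                raise SchemaError(f"unknown group labels {sorted(bad_groups)}")
            if self.kind == "raw":
                bad_tp = set(self.sample_meta["timepoint"]) - set(TIMEPOINTS)
                if bad_tp:
                    raise SchemaError(f"unknown timepoints {sorted(bad_tp)}")
        dup = self.sample_meta.duplicated(subset=["animal_id", "timepoint"])
        if dup.any():
            rows = self.sample_meta.loc[dup, ["animal_id", "timepoint"]]
            raise IntegrityError(
                f"duplicate (animal, timepoint) rows: {rows.to_records(index=False).tolist()}")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise DataValidationError("values contain non-finite entries")
        if self.kind == "raw":
            with np.errstate(invalid="ignore"):
                if np.any(self.values < 0):
                    raise DataValidationError("raw concentrations must be non-negative")

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def compartment(self) -> str:
        if not len(self.sample_meta):
            raise SchemaError("empty dataset has no compartment")
        return str(self.sample_meta["compartment"].iloc[0])

    def subset(self, row_mask: np.ndarray) -> "MetabolomicsDataset":
        row_mask = np.asarray(row_mask)
        if row_mask.dtype != bool:
            idx = row_mask
        else:
            idx = np.flatnonzero(row_mask)
        return dataclasses.replace(
            self,
            values=self.values[idx],
            sample_meta=self.sample_meta.iloc[idx].reset_index(drop=True),
        )

    def with_values(self, values: np.ndarray, units: str | None = None,
                    kind: str | None = None) -> "MetabolomicsDataset":
        return dataclasses.replace(
            self, values=values,
            units=self.units if units is None else units,
            kind=self.kind if kind is None else kind)

    def to_long(self) -> pd.DataFrame:
        """Long/tidy frame, row-major in sample order then metabolite order."""
        n, p = self.values.shape
        meta = self.sample_meta
        has_flow = "urine_output" in meta.columns
        frame = pd.DataFrame({
            "animal_id": np.repeat(meta["animal_id"].to_numpy(), p),
            "group": np.repeat(meta["group"].to_numpy(), p),
            "compartment": np.repeat(meta["compartment"].to_numpy(), p) if n else
                           np.empty(0, dtype=object),
            "timepoint": np.repeat(meta["timepoint"].to_numpy(), p),
            "urine_output": (np.repeat(meta["urine_output"].to_numpy(dtype=float), p)
                             if has_flow else np.full(n * p, np.nan)),
            "metabolite": np.tile(np.asarray(self.metabolite_names, dtype=object), n),
            "value": self.values.ravel(),
        })
        return frame

    def to_wide(self) -> pd.DataFrame:
        meta_cols = [c for c in ("animal_id", "group", "compartment", "timepoint",
                                 "urine_output") if c in self.sample_meta.columns]
        wide = self.sample_meta[meta_cols].copy()
        for j, name in enumerate(self.metabolite_names):
            wide[name] = self.values[:, j]
        return wide

    def equals(self, other: "MetabolomicsDataset", rtol: float = 1e-9) -> bool:
        if self.metabolite_names != other.metabolite_names:
            return False
        if self.values.shape != other.values.shape:
            return False
        a, b = self.values, other.values
        if not (np.isnan(a) == np.isnan(b)).all():
            return False
        ok = np.isclose(a, b, rtol=rtol, atol=0.0, equal_nan=True).all()
        keys = ["animal_id", "group", "compartment", "timepoint"]
        return bool(ok) and self.sample_meta[keys].equals(other.sample_meta[keys])


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(path: str | Path, compartment: str | None = None,
                 units: str | None = None) -> MetabolomicsDataset:
    """Read a long-format delimited file into a :class:`MetabolomicsDataset`.

    Empty value cells are recorded as missing (NaN), never as zeros.  The
    file must contain a single compartment unless ``compartment`` selects
    one.  Negative values are rejected for raw timepoint data; interval
    files (timepoint labels like ``"S45-B"``) are sign-free.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"animal_id": str, "group": str,
                                               "compartment": str, "timepoint": str,
                                               "metabolite": str})
    except FileNotFoundError:
        raise
    required = {"animal_id", "group", "compartment", "timepoint", "metabolite", "value"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path.name}: non-numeric value cell ({exc})") from exc

    if compartment is not None:
        df = df[df["compartment"] == compartment]
        if not len(df):
            raise SchemaError(f"{path.name}: no rows for compartment {compartment!r}")
    if len(df):
        comps = df["compartment"].unique()
        if len(comps) > 1:
            raise IntegrityError(
                f"{path.name}: multiple compartments {sorted(comps)}; pass compartment=...")

    if not len(df):
        return MetabolomicsDataset(
            values=np.empty((0, 0)), metabolite_names=[],
            sample_meta=pd.DataFrame(columns=list(_META_REQUIRED)),
            units=units or "")

    dup = df.duplicated(subset=["animal_id", "timepoint", "metabolite"])
    if dup.any():
        rows = df.loc[dup, ["animal_id", "timepoint", "metabolite"]].iloc[0]
        raise IntegrityError(f"{path.name}: duplicate cell for "
                             f"({rows.animal_id}, {rows.timepoint}, {rows.metabolite})")

    names = list(dict.fromkeys(df["metabolite"]))
    col_of = {m: j for j, m in enumerate(names)}
    sample_keys = list(dict.fromkeys(zip(df["animal_id"], df["timepoint"])))
    row_of = {k: i for i, k in enumerate(sample_keys)}

    n, p = len(sample_keys), len(names)
    values = np.full((n, p), np.nan)
    rows = df[["animal_id", "timepoint"]].apply(tuple, axis=1).map(row_of).to_numpy()
    cols = df["metabolite"].map(col_of).to_numpy()
    values[rows, cols] = df["value"].to_numpy(dtype=float)

    first = df.drop_duplicates(subset=["animal_id", "timepoint"]).set_index(
        df.drop_duplicates(subset=["animal_id", "timepoint"])[["animal_id", "timepoint"]]
        .apply(tuple, axis=1))
    meta = pd.DataFrame({
        "animal_id": [k[0] for k in sample_keys],
        "group": [first.loc[[k], "group"].iloc[0] for k in sample_keys],
        "compartment": [first.loc[[k], "compartment"].iloc[0] for k in sample_keys],
        "timepoint": [k[1] for k in sample_keys],
    })
    if "urine_output" in df.columns:
        flow = pd.to_numeric(df["urine_output"], errors="coerce")
        first_flow = flow.groupby([df["animal_id"], df["timepoint"]]).first()
        meta["urine_output"] = [first_flow.get((k[0], k[1]), np.nan) for k in sample_keys]
        if meta["urine_output"].isna().all():
            meta = meta.drop(columns=["urine_output"])

    kind = "difference" if any("-" in t for t in meta["timepoint"]) else "raw"
    comp = meta["compartment"].iloc[0]
    if units is None:
        units = RAW_UNITS.get(comp, "")
    return MetabolomicsDataset(values=values, metabolite_names=names,
                               sample_meta=meta, units=units, kind=kind)


def write_dataset(ds: MetabolomicsDataset, path: str | Path) -> Path:
    """Write long-format delimited text that :func:`read_dataset` restores.

    Values are written with 12 significant digits so the round trip is
    lossless to ~1e-9 relative; a second write of the re-read dataset is
    byte-identical.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    long = ds.to_long()
    if "urine_output" in ds.sample_meta.columns:
        cols = list(LONG_COLUMNS)
    else:
        cols = [c for c in LONG_COLUMNS if c != "urine_output"]
    try:
        long[cols].to_csv(path, sep=sep, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write dataset to {path}: {exc}") from exc
    return path


def write_wide(ds: MetabolomicsDataset, path: str | Path) -> Path:
    """Wide samples-by-metabolites matrix with leading metadata columns."""
    path = Path(path)
    ds.to_wide().to_csv(path, sep=_delimiter_for(path), index=False,
                        float_format="%.12g")
    return path


def read_wide(path: str | Path) -> pd.DataFrame:
    """Read a wide matrix written by :func:`write_wide` (metadata + metabolites)."""
    path = Path(path)
    return pd.read_csv(path, sep=_delimiter_for(path),
                       dtype={"animal_id": str, "group": str,
                              "compartment": str, "timepoint": str})
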