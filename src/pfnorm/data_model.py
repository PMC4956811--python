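"""Tidy long-format data structures for assay time series.

The canonical container is :class:`LongTable`: one row per
``(patient_id, timepoint, attribute)`` measurement, with the timepoint
carrying a total order. A wide view (one row per patient/timepoint, one
column per attribute) is derived on demand with :func:`pivot_wide` and is
the input shape for correlation analysis.

Missing measurements are *absent rows*, never sentinel values, so that
group statistics computed downstream are untouched by missingness
conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColumnMap",
    "LongTable",
    "LoadError",
    "ValidationError",
    "read_long_table",
    "write_long_table",
    "pivot_wide",
    "pivot_long",
    "derive_pltem",
    "DEFAULT_PLTEM_PARAMETERS",
]

logger = logging.getLogger(__name__)

#: Parameter families for which the platelet-contribution channel is derived
#: by default. Clotting/formation times and lysis are excluded: subtracting
#: times is of doubtful meaning. Overridable in :func:`derive_pltem`.
DEFAULT_PLTEM_PARAMETERS: tuple[str, ...] = ("A5", "A10", "A20", "Alpha", "MCF")

_CANONICAL_COLUMNS = ["patient_id", "timepoint", "attribute", "value", "unit"]


class LoadError(ValueError):
    """Raised when an input file cannot be mapped onto the long schema."""


class ValidationError(ValueError):
    """Raised when table contents violate a structural invariant."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from file header names to the canonical long columns."""

    patient: str = "patient"
    timepoint: str = "timepoint"
    attribute: str = "attribute"
    value: str = "value"
    unit: str = "unit"

    def required(self) -> dict[str, str]:
        return {
            self.patient: "patient_id",
            self.timepoint: "timepoint",
            self.attribute: "attribute",
            self.value: "value",
        }


def _parse_float(v) -> float:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    s = str(v).strip()
    return np.nan if s == "" else float(s)


def _default_timepoint_order(labels: Iterable[str]) -> list[str]:
    """S1 < S2 < S3 when only those labels occur, else first appearance."""
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    canonical = ["S1", "S2", "S3"]
    if set(seen) <= set(canonical) and seen:
        return [t for t in canonical if t in set(seen)]
    return seen


class LongTable:
    """Validated tidy record set of assay measurements.

    Parameters
    ----------
    df : DataFrame with columns patient_id, timepoint, attribute, value
        and optionally unit. Rows with missing value are dropped (missing
        measurements are absent rows).
    timepoint_order : explicit total order of timepoint labels; defaults
        to S1 < S2 < S3 when applicable, otherwise first appearance.
    """

    def __init__(self, df: pd.DataFrame, timepoint_order: Sequence[str] | None = None):
        df = df.copy()
        for col in ("patient_id", "timepoint", "attribute", "value"):
            if col not in df.columns:
                raise ValidationError(f"missing required column: {col!r}")
        if "unit" not in df.columns:
            df["unit"] = pd.NA
        df = df[_CANONICAL_COLUMNS]

        raw = df["value"]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            offenders = df.loc[bad, "value"].astype(str).unique()[:5].tolist()
            raise ValidationError(f"non-numeric values: {offenders}")
        if raw.dtype == object:
            # Python float() is correctly rounded; pandas' fast parser can be
            # off by one ulp, which would break exact CSV round-trips
            df["value"] = raw.map(_parse_float).astype(float)
        else:
            df["value"] = coerced.astype(float)
        df = df.dropna(subset=["value"]).reset_index(drop=True)

        df["patient_id"] = df["patient_id"].astype(str)
        df["attribute"] = df["attribute"].astype(str)
        labels = df["timepoint"].astype(str)
        if timepoint_order is None:
            order = _default_timepoint_order(labels)
        else:
            order = list(dict.fromkeys(str(t) for t in timepoint_order))
            unknown = sorted(set(labels) - set(order))
            if unknown:
                raise ValidationError(f"timepoints not in supplied order: {unknown}")
        df["timepoint"] = pd.Categorical(labels, categories=order, ordered=True)

        dup = df.duplicated(subset=["patient_id", "timepoint", "attribute"], keep=False)
        if dup.any():
            triples = (
                df.loc[dup, ["patient_id", "timepoint", "attribute"]]
                .astype(str)
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise ValidationError(f"duplicate (patient, timepoint, attribute) triples: {sorted(triples)}")

        self._df = df

    # ------------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """Backing frame (copy-on-write semantics: treat as read-only)."""
        return self._df

    @property
    def timepoint_order(self) -> list[str]:
        return list(self._df["timepoint"].cat.categories)

    @property
    def attributes(self) -> list[str]:
        return sorted(self._df["attribute"].unique())

    @property
    def patients(self) -> list[str]:
        return sorted(self._df["patient_id"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongTable):
            return NotImplemented
        a = self._df.sort_values(["patient_id", "timepoint", "attribute"]).reset_index(drop=True)
        b = other._df.sort_values(["patient_id", "timepoint", "attribute"]).reset_index(drop=True)
        if self.timepoint_order != other.timepoint_order:
            return False
        return a.drop(columns="unit").equals(b.drop(columns="unit"))

    def time_index(self) -> pd.Series:
        """Integer code 0, 1, 2, ... of each row's timepoint."""
        return self._df["timepoint"].cat.codes

    def replace_values(self, values: pd.Series) -> "LongTable":
        """New table with the value column replaced (index-aligned)."""
        df = self._df.copy()
        df["value"] = values
        df = df.dropna(subset=["value"])
        return LongTable(df, timepoint_order=self.timepoint_order)

    def subset(self, attributes: Sequence[str]) -> "LongTable":
        keep = self._df["attribute"].isin(list(attributes))
        return LongTable(self._df[keep], timepoint_order=self.timepoint_order)


def read_long_table(
    source: str | IO[str],
    timepoint_order: Sequence[str] | None = None,
    column_map: ColumnMap | None = None,
    delimiter: str = ",",
) -> LongTable:
    """Read a delimited text file into a validated :class:`LongTable`.

    Raises :class:`LoadError` naming any required column absent from the
    header, and :class:`ValidationError` for duplicate triples or
    non-numeric values.
    """
    cmap = column_map or ColumnMap()
    try:
        raw = pd.read_csv(source, sep=delimiter, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LoadError(f"cannot parse delimited input: {exc}") from exc

    missing = [src for src in cmap.required() if src not in raw.columns]
    if missing:
        raise LoadError(f"missing required column(s) in header: {missing}")

    rename = dict(cmap.required())
    if cmap.unit in raw.columns:
        rename[cmap.unit] = "unit"
    df = raw.rename(columns=rename)
    return LongTable(df, timepoint_order=timepoint_order)


def write_long_table(table: LongTable, target: str | IO[str], delimiter: str = ",") -> None:
    """Write the canonical CSV dialect (header, empty field = missing unit)."""
    out = table.df.copy()
    out.columns = ["patient", "timepoint", "attribute", "value", "unit"]
    out.to_csv(target, sep=delimiter, index=False)


def pivot_wide(table: LongTable) -> pd.DataFrame:
    """Wide view: index (patient_id, timepoint), one column per attribute."""
    wide = table.df.pivot(index=["patient_id", "timepoint"], columns="attribute", values="value")
    wide = wide.dropna(how="all")
    wide.columns.name = None
    return wide


def pivot_long(wide: pd.DataFrame, timepoint_order: Sequence[str] | None = None) -> LongTable:
    """Inverse of :func:`pivot_wide`; missing cells produce no rows."""
    long = wide.stack().rename("value").reset_index()
    long.columns = ["patient_id", "timepoint", "attribute", "value"]
    if timepoint_order is None and isinstance(wide.index.get_level_values("timepoint"), pd.CategoricalIndex):
        timepoint_order = list(wide.index.get_level_values("timepoint").categories)
    return LongTable(long, timepoint_order=timepoint_order)


def derive_pltem(
    table: LongTable,
    parameters: Sequence[str] = DEFAULT_PLTEM_PARAMETERS,
) -> LongTable:
    """Append derived platelet-contribution rows ``"X PLTEM"``.

    For each parameter family ``X`` in *parameters*, computes
    ``value("X EXTEM") - value("X FIBTEM")`` at every (patient, timepoint)
    where both operands are present; pairs with either operand missing
    produce no row and are logged. A requested family with zero computable
    pairs yields a warning, not a failure. Existing rows are never mutated.
    """
    df = table.df
    new_rows: list[pd.DataFrame] = []
    for param in parameters:
        ext_name, fib_name, plt_name = (f"{param} EXTEM", f"{param} FIBTEM", f"{param} PLTEM")
        if plt_name in set(df["attribute"]):
            raise ValidationError(f"attribute {plt_name!r} already present; refusing to overwrite")
        ext = df[df["attribute"] == ext_name].set_index(["patient_id", "timepoint"])
        fib = df[df["attribute"] == fib_name].set_index(["patient_id", "timepoint"])
        common = ext.index.intersection(fib.index)
        skipped = ext.index.symmetric_difference(fib.index)
        for key in skipped:
            logger.info("derive_pltem: %s missing an operand at %s", param, key)
        if len(common) == 0:
            logger.warning("derive_pltem: no computable (EXTEM, FIBTEM) pairs for %r", param)
            continue
        out = pd.DataFrame(
            {
                "value": ext.loc[common, "value"] - fib.loc[common, "value"],
                "unit": ext.loc[common, "unit"],
                "attribute": plt_name,
            }
        ).reset_index()
        new_rows.append(out[_CANONICAL_COLUMNS])

    if not new_rows:
        return LongTable(df, timepoint_order=table.timepoint_order)
    combined = pd.concat([df] + new_rows, ignore_index=True)
    return LongTable(combined, timepoint_order=table.timepoint_order)
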