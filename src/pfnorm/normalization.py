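"""Group-wise normalization transforms for long assay tables.

Four transforms (z-standardization, range scaling, proportion-of-sum,
robust interquartile scaling), each applicable under one of three grouping
scopes:

``all``
    one group holding every non-missing value in the table,
``per_attribute``
    one group per attribute, pooling all patients and timepoints,
``per_timepoint``
    one group per timepoint, pooling all patients and attributes.

The z, range and iqr transforms are strictly increasing maps within a
group (given non-degenerate spread), so any rank statistic computed
within a group — and, for ``per_attribute`` scope, any cross-attribute
rank correlation over pooled samples — is preserved exactly. Proportion
scaling is increasing only when the group sum is positive.

Conventions (documented interpretations where the method is named but not
fully specified): the standard deviation uses the sample (n-1)
denominator; quantiles use linear interpolation between order statistics;
the interquartile method is robust scaling, ``(x - median) / (Q3 - Q1)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Hashable, Literal

import numpy as np
import pandas as pd

from .data_model import LongTable

__all__ = [
    "Method",
    "Scope",
    "NormalizationSpec",
    "GroupStatistics",
    "DegenerateGroupError",
    "NormalizationReport",
    "partition_groups",
    "group_statistics",
    "z_transform",
    "range_transform",
    "proportion_transform",
    "iqr_transform",
    "normalize",
]

logger = logging.getLogger(__name__)

Method = Literal["z", "range", "proportion", "iqr"]
Scope = Literal["all", "per_attribute", "per_timepoint"]
DegeneratePolicy = Literal["error", "skip", "zero"]

_METHODS = ("z", "range", "proportion", "iqr")
_SCOPES = ("all", "per_attribute", "per_timepoint")


class DegenerateGroupError(ValueError):
    """A group has no usable spread (or sum) for the requested transform."""


@dataclass(frozen=True)
class NormalizationSpec:
    """Method + scope + method parameters; fully determines a run.

    ``range_lo``/``range_hi`` apply to the range method only; ``clamp_z``
    (off by default) clips standardized values to ``[-b, +b]`` — note that
    clamping destroys strict monotonicity at the tails and therefore the
    rank-preservation guarantee.
    """

    method: Method
    scope: Scope
    range_lo: float = 0.0
    range_hi: float = 1.0
    clamp_z: float | None = None
    degenerate: DegeneratePolicy = "skip"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if self.scope not in _SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}; expected one of {_SCOPES}")
        if self.method == "range" and not self.range_lo < self.range_hi:
            raise ValueError(f"range_lo must be < range_hi (got {self.range_lo}, {self.range_hi})")
        if self.clamp_z is not None and self.clamp_z <= 0:
            raise ValueError("clamp_z must be positive")
        if self.degenerate not in ("error", "skip", "zero"):
            raise ValueError(f"unknown degenerate policy {self.degenerate!r}")


@dataclass(frozen=True)
class GroupStatistics:
    """Summary statistics of one normalization group."""

    key: Hashable
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    total: float
    q1: float
    q3: float
    median: float


def group_statistics(key: Hashable, x: np.ndarray) -> GroupStatistics:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return GroupStatistics(
        key=key,
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        total=float(np.sum(x)),
        q1=float(q1),
        q3=float(q3),
        median=float(med),
    )


def partition_groups(table: LongTable, scope: Scope) -> list[tuple[Hashable, np.ndarray]]:
    """Split the table's values into normalization groups.

    Returns ``(group_key, values)`` pairs; the groups are disjoint and
    jointly exhaust the non-missing values.
    """
    if scope == "all":
        return [("all", table.df["value"].to_numpy())]
    if scope == "per_attribute":
        return [
            (attr, sub["value"].to_numpy())
            for attr, sub in table.df.groupby("attribute", sort=True, observed=True)
        ]
    if scope == "per_timepoint":
        return [
            (str(tp), sub["value"].to_numpy())
            for tp, sub in table.df.groupby("timepoint", sort=True, observed=True)
        ]
    raise ValueError(f"unknown scope {scope!r}")


# ----------------------------------------------------------------------
# vector transforms


def z_transform(x: np.ndarray, clamp: float | None = None) -> np.ndarray:
    """Standardize to mean 0, sample sd 1: ``(x - mean) / sd``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateGroupError("z-transform needs at least 2 values")
    s = np.std(x, ddof=1)
    if s == 0:
        raise DegenerateGroupError("z-transform undefined for constant group (sd = 0)")
    z = (x - np.mean(x)) / s
    if clamp is not None:
        z = np.clip(z, -clamp, clamp)
    return z


def range_transform(x: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine rescale onto ``[lo, hi]`` with the attained extremes mapped exactly."""
    x = np.asarray(x, dtype=float)
    if not lo < hi:
        raise ValueError(f"lo must be < hi (got {lo}, {hi})")
    xmin, xmax = np.min(x), np.max(x)
    if xmax == xmin:
        raise DegenerateGroupError("range transform undefined for constant group (max = min)")
    return lo + (x - xmin) * ((hi - lo) / (xmax - xmin))


def proportion_transform(x: np.ndarray) -> np.ndarray:
    """Divide each value by the group total so outputs sum to one.

    A negative total makes the map order-reversing; a warning is emitted
    because rank statistics are flipped in sign.
    """
    x = np.asarray(x, dtype=float)
    total = np.sum(x)
    if total == 0:
        raise DegenerateGroupError("proportion transform undefined for zero-sum group")
    if total < 0:
        warnings.warn(
            "proportion transform over a negative-sum group is order-reversing",
            UserWarning,
            stacklevel=2,
        )
    return x / total


def iqr_transform(x: np.ndarray) -> np.ndarray:
    """Robust scaling: ``(x - median) / (Q3 - Q1)``; median 0, IQR 1 out."""
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if q3 == q1:
        raise DegenerateGroupError("iqr transform undefined when Q3 = Q1")
    return (x - med) / (q3 - q1)


# ----------------------------------------------------------------------
# table-level driver


@dataclass
class NormalizationReport:
    """Per-group statistics and degeneracy outcomes of one run."""

    spec: NormalizationSpec
    groups: list[GroupStatistics]
    degenerate_groups: list[str]
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "groups": [dataclasses.asdict(g) for g in self.groups],
            "degenerate_groups": self.degenerate_groups,
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _apply(spec: NormalizationSpec, x: np.ndarray) -> np.ndarray:
    if spec.method == "z":
        return z_transform(x, clamp=spec.clamp_z)
    if spec.method == "range":
        return range_transform(x, spec.range_lo, spec.range_hi)
    if spec.method == "proportion":
        return proportion_transform(x)
    return iqr_transform(x)


def normalize(table: LongTable, spec: NormalizationSpec) -> tuple[LongTable, NormalizationReport]:
    """Apply ``spec`` group-wise over the table.

    Values are replaced within each group of ``partition_groups(table,
    spec.scope)``; patient/timepoint/attribute labels are untouched and
    missing rows stay missing. Degenerate groups follow ``spec.degenerate``:
    ``error`` raises, ``skip`` (default) drops the group's rows as missing
    with a warning, ``zero`` writes zeros.
    """
    df = table.df
    if spec.scope == "all":
        grouper = pd.Series("all", index=df.index)
    elif spec.scope == "per_attribute":
        grouper = df["attribute"]
    else:
        grouper = df["timepoint"]

    out = pd.Series(np.nan, index=df.index, dtype=float)
    stats: list[GroupStatistics] = []
    degenerate: list[str] = []
    notes: list[str] = []

    for key, idx in df.groupby(grouper, sort=True, observed=True).groups.items():
        x = df.loc[idx, "value"].to_numpy()
        stats.append(group_statistics(str(key), x))
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                out.loc[idx] = _apply(spec, x)
            for w in caught:
                notes.append(f"group {key!s}: {w.message}")
        except DegenerateGroupError as exc:
            if spec.degenerate == "error":
                raise DegenerateGroupError(f"group {key!s}: {exc}") from exc
            degenerate.append(str(key))
            msg = f"degenerate group {key!s} ({exc}); policy={spec.degenerate}"
            notes.append(msg)
            logger.warning(msg)
            if spec.degenerate == "zero":
                out.loc[idx] = 0.0
            # "skip": leave NaN -> rows dropped (missing)

    report = NormalizationReport(spec=spec, groups=stats, degenerate_groups=degenerate, warnings=notes)
    return table.replace_values(out), report
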