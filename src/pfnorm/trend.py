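"""Pooled polynomial trend fitting of attribute values against the
ordered time index.

Time is encoded as consecutive integer indices 0, 1, 2, ... of the ordered
timepoints (the sampling axis is categorical-ordered; elapsed hours are
not used). The fit pools all patients' points at each index (optionally
per-patient means first). Model degrees of freedom are 1 + degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import LongTable

__all__ = ["TrendFit", "TrendError", "fit_trend", "evaluate_trend"]

#: Default polynomial degree — the maximum supported by 3 distinct timepoints.
DEFAULT_DEGREE = 2


class TrendError(ValueError):
    pass


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares polynomial fit of one attribute over time.

    ``coefficients`` are in ascending powers of the time index;
    ``model_df = 1 + degree`` and ``residual_df = n_points - model_df``.
    """

    attribute: str
    degree: int
    coefficients: tuple[float, ...]
    n_points: int
    r_squared: float
    time_levels: tuple[str, ...] = field(default=())

    @property
    def model_df(self) -> int:
        return self.degree + 1

    @property
    def residual_df(self) -> int:
        return self.n_points - self.model_df

    @property
    def max_index(self) -> int:
        return len(self.time_levels) - 1 if self.time_levels else self.degree


def fit_trend(
    table: LongTable,
    attribute: str,
    degree: int = DEFAULT_DEGREE,
    per_patient_mean: bool = False,
) -> TrendFit:
    """Fit a degree-``degree`` polynomial to one attribute's pooled values.

    All patient-level points are pooled per time index (set
    ``per_patient_mean`` to average each patient's replicates first —
    with one value per patient per timepoint the two are identical).
    When the number of distinct time indices equals ``degree + 1`` the
    fitted curve interpolates each index's pooled mean exactly.

    A constant attribute yields zero slope coefficients and, by
    convention, ``r_squared = 0``.
    """
    if degree < 1:
        raise TrendError(f"degree must be >= 1, got {degree}")
    sub = table.df[table.df["attribute"] == attribute]
    if sub.empty:
        raise TrendError(f"attribute not present: {attribute!r}")
    x = sub["timepoint"].cat.codes.to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    if per_patient_mean:
        g = pd.DataFrame({"p": sub["patient_id"], "x": x, "y": y}).groupby(["p", "x"])["y"].mean()
        x = g.index.get_level_values("x").to_numpy(dtype=float)
        y = g.to_numpy()

    n_distinct = len(np.unique(x))
    if n_distinct < degree + 1:
        raise TrendError(
            f"{n_distinct} distinct time point(s) support at most degree {n_distinct - 1}"
        )

    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    return TrendFit(
        attribute=attribute,
        degree=degree,
        coefficients=tuple(float(c) for c in coeffs),
        n_points=len(y),
        r_squared=r2,
        time_levels=tuple(table.timepoint_order),
    )


def evaluate_trend(fit: TrendFit, grid: np.ndarray, extrapolate: bool = False) -> np.ndarray:
    """Evaluate the fitted polynomial on ``grid`` time indices.

    Points outside ``[0, max index]`` require ``extrapolate=True``.
    """
    grid = np.asarray(grid, dtype=float)
    if not extrapolate and (np.any(grid < 0) or np.any(grid > fit.max_index)):
        raise TrendError(
            f"grid outside [0, {fit.max_index}]; pass extrapolate=True to allow"
        )
    return np.polynomial.polynomial.polyval(grid, np.asarray(fit.coefficients))
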