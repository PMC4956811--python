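"""Spearman rank correlation between attribute pairs, with p-values and
the study's strength bands (|rho| > 0.40 strong, 0.30-0.40 moderate).

Correlations pool all (patient, timepoint) samples; missing data are
handled by pairwise (complete-pairs) deletion. Two p-value routes are
provided: the usual t approximation on n-2 degrees of freedom, and —
as a brute-force oracle for small tie-free samples — exact enumeration
of all n! rank permutations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelationError",
    "PermutationRefusedError",
    "EXACT_PERM_MAX_N",
    "rank_values",
    "spearman_rho",
    "spearman_p",
    "classify_strength",
    "correlation_matrix",
]

PMethod = Literal["t_approx", "exact_perm"]

#: Largest n for which exact permutation enumeration (n! null values) is allowed.
EXACT_PERM_MAX_N = 8


class UndefinedCorrelationError(ValueError):
    """Fewer than 2 complete pairs, or zero rank variance on one side."""


class PermutationRefusedError(ValueError):
    """exact_perm requested beyond the enumeration threshold."""


@dataclass(frozen=True)
class CorrelationResult:
    """One attribute pair's rank correlation."""

    attribute_a: str
    attribute_b: str
    rho: float
    p_value: float
    n: int
    strength: str


def rank_values(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Ranks 1..n, ties receiving the average of the tied positions."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank an empty vector")
    return stats.rankdata(x, method="average")


def _complete_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Pearson correlation of the two rank vectors (complete pairs only)."""
    x, y = _complete_pairs(np.asarray(x, float), np.asarray(y, float))
    if x.size < 2:
        raise UndefinedCorrelationError(f"need >= 2 complete pairs, got {x.size}")
    rx, ry = rank_values(x), rank_values(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero rank variance (constant vector)")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


@lru_cache(maxsize=8)
def _null_rho_distribution(n: int) -> np.ndarray:
    """All n! Spearman rho values of tie-free rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1)
    out = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(base)):
        d = base - np.asarray(perm)
        out[i] = 1.0 - 6.0 * np.dot(d, d) / denom
    return out


def spearman_p(
    rho: float,
    n: int,
    method: PMethod = "t_approx",
    has_ties: bool = False,
) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    ``t_approx`` uses ``t = rho * sqrt((n-2) / (1 - rho^2))`` on n-2 df.
    ``exact_perm`` enumerates the full permutation null (tie-free case
    only) and is limited to n <= ``EXACT_PERM_MAX_N``; with ties the
    enumeration null is ill-defined, so it falls back to t_approx with a
    warning.
    """
    if n < 3:
        raise UndefinedCorrelationError(f"p-value undefined for n={n} < 3")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho out of range: {rho}")

    if method == "exact_perm":
        if has_ties:
            warnings.warn(
                "exact permutation null is ill-defined with ties; using t approximation",
                UserWarning,
                stacklevel=2,
            )
            method = "t_approx"
        elif n > EXACT_PERM_MAX_N:
            raise PermutationRefusedError(
                f"exact enumeration refused for n={n} > {EXACT_PERM_MAX_N}"
            )

    if method == "exact_perm":
        null = _null_rho_distribution(n)
        return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))

    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def classify_strength(rho: float) -> str:
    """Strength label: |rho| > 0.40 strong, 0.30 <= |rho| <= 0.40 moderate,
    else weak. (The value 0.40 itself is assigned to moderate so the bands
    tile [0, 1].)"""
    a = abs(rho)
    if a > 1.0:
        raise ValueError(f"|rho| > 1: {rho}")
    if a > 0.40:
        return "strong"
    if a >= 0.30:
        return "moderate"
    return "weak"


def correlation_matrix(
    wide: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str],
    p_method: PMethod = "t_approx",
) -> list[CorrelationResult]:
    """One :class:`CorrelationResult` per (target, reference) pair.

    ``wide`` is the pivoted view (rows = pooled patient/timepoint samples,
    columns = attributes). Complete-pairs n is reported per pair.
    """
    for name in list(targets) + list(references):
        if name not in wide.columns:
            raise KeyError(f"attribute not present in table: {name!r}")

    results: list[CorrelationResult] = []
    for a in targets:
        for b in references:
            x, y = _complete_pairs(wide[a].to_numpy(), wide[b].to_numpy())
            rho = spearman_rho(x, y)
            ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
            p = spearman_p(rho, n=len(x), method=p_method, has_ties=ties)
            results.append(
                CorrelationResult(
                    attribute_a=a,
                    attribute_b=b,
                    rho=rho,
                    p_value=p,
                    n=len(x),
                    strength=classify_strength(rho),
                )
            )
    return results


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tabular view of correlation results (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "attribute_a": r.attribute_a,
                "attribute_b": r.attribute_b,
                "rho": r.rho,
                "p_value": r.p_value,
                "n": r.n,
                "strength": r.strength,
            }
            for r in results
        ]
    )
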