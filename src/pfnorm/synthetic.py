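"""Gaussian-copula generator for perioperative platelet-function-like
study tables.

The generator draws, for every (patient, timepoint) sample, a latent
multivariate normal with a correlation matrix chosen so that the pushed-
forward values attain prescribed pairwise Spearman correlations
(``r_latent = 2 sin(pi * rho_s / 6)``). Each latent coordinate is pushed
through a truncated-normal marginal whose mean/sd come either from an
explicit pair or from a printed "normal range" read as a central 95%
interval (``mean = midpoint``, ``sd = width / 3.92``), truncated at a
physiologic lower bound (default 0).

A per-attribute multiplicative time-effect profile scales the marginal
*mean* per timepoint (default 1.0, 0.6, 0.8: dip after bypass, partial
recovery) without touching the copula, so within-timepoint rank structure
is preserved while a pooled temporal trend appears.

Sum-composed attributes (by default ``MCF EXTEM = MCF FIBTEM + MCF
PLTEM``, with the PLTEM addend hidden) keep the subtraction identity of
the derived platelet channel exact: running the data model's
``derive_pltem`` on generated output recovers the generator's hidden
addend bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LongTable, pivot_wide
from .correlation import spearman_rho

__all__ = [
    "MarginalSpec",
    "SyntheticConfig",
    "GeneratorReport",
    "ConfigError",
    "default_config",
    "config_from_dict",
    "spearman_to_latent",
    "nearest_psd",
    "build_latent_matrix",
    "sample_copula",
    "generate_study",
    "inject_missing",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one latent attribute.

    Provide either ``mean`` and ``sd``, or ``normal_range`` (interpreted
    as a central 95% interval). Values are truncated at ``lower_bound``.
    """

    name: str
    unit: str | None = None
    mean: float | None = None
    sd: float | None = None
    normal_range: tuple[float, float] | None = None
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.normal_range is not None:
            lo, hi = self.normal_range
            if not lo < hi:
                raise ConfigError(f"{self.name}: normal_range must be (lo, hi) with lo < hi")
        elif self.mean is None or self.sd is None:
            raise ConfigError(f"{self.name}: need mean+sd or normal_range")
        if self.sd is not None and self.sd <= 0:
            raise ConfigError(f"{self.name}: sd must be positive")

    @property
    def resolved_mean(self) -> float:
        if self.mean is not None:
            return float(self.mean)
        lo, hi = self.normal_range  # type: ignore[misc]
        return (lo + hi) / 2.0

    @property
    def resolved_sd(self) -> float:
        if self.sd is not None:
            return float(self.sd)
        lo, hi = self.normal_range  # type: ignore[misc]
        return (hi - lo) / 3.92

    def ppf(self, u: np.ndarray, mean_scale: float = 1.0) -> np.ndarray:
        """Inverse CDF of the (possibly mean-scaled) truncated normal."""
        loc = self.resolved_mean * mean_scale
        sd = self.resolved_sd
        a = (self.lower_bound - loc) / sd
        return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=loc, scale=sd)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic study draw."""

    n_patients: int = 20
    timepoints: tuple[str, ...] = ("S1", "S2", "S3")
    attributes: tuple[MarginalSpec, ...] = ()
    spearman_targets: tuple[tuple[str, str, float], ...] = ()
    compose: tuple[tuple[str, str, tuple[str, ...]], ...] = ()
    #: latent attributes consumed by a composition and not emitted themselves
    hidden: tuple[str, ...] = ()
    time_effect: tuple[tuple[str, tuple[float, ...]], ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        names = [m.name for m in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate attribute names in config")
        composed = {name for name, _unit, _parts in self.compose}
        for name, _unit, parts in self.compose:
            for p in parts:
                if p not in names:
                    raise ConfigError(f"composition {name!r} references unknown latent {p!r}")
        for h in self.hidden:
            if h not in names:
                raise ConfigError(f"hidden attribute {h!r} is not a latent attribute")
        # a PLTEM channel must come from derive_pltem on emitted sums, never
        # be emitted directly alongside a composition
        emitted = (set(names) - set(self.hidden)) | composed
        if self.compose and any("PLTEM" in a for a in emitted):
            raise ConfigError(
                "PLTEM-named attribute would be emitted while sum-composition "
                "(auto-derivation) is enabled; hide it or drop the composition"
            )
        for a, b, rho in self.spearman_targets:
            if abs(rho) > 1:
                raise ConfigError(f"target Spearman out of range for ({a}, {b}): {rho}")
            if a not in names or b not in names:
                raise ConfigError(f"spearman target names unknown latent: ({a}, {b})")
        for name, profile in self.time_effect:
            if name != "*" and name not in names:
                raise ConfigError(f"time_effect names unknown latent {name!r}")
            if len(profile) != len(self.timepoints):
                raise ConfigError(f"time_effect for {name!r} must have {len(self.timepoints)} entries")
            if any(f <= 0 for f in profile):
                raise ConfigError("time_effect factors must be positive")

    # ------------------------------------------------------------------
    @property
    def latent_names(self) -> list[str]:
        return [m.name for m in self.attributes]

    @property
    def emitted_names(self) -> list[str]:
        kept = [n for n in self.latent_names if n not in set(self.hidden)]
        return kept + [name for name, _unit, _parts in self.compose]

    def effect_profile(self, name: str) -> tuple[float, ...]:
        table = dict((k, v) for k, v in self.time_effect)
        if name in table:
            return table[name]
        if "*" in table:
            return table["*"]
        return tuple(1.0 for _ in self.timepoints)


@dataclass
class GeneratorReport:
    """Realized statistics of one generated study (reproducible per config)."""

    seed: int
    n_rows: int
    realized_means: dict[str, float]
    realized_sds: dict[str, float]
    realized_spearman: dict[str, float]
    time_effect: dict[str, list[float]]
    #: ground truth for derived channels: emitted minuend minus emitted
    #: subtrahend, computed with the same float ops derive_pltem uses
    derived_truth: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_rows": self.n_rows,
            "realized_means": self.realized_means,
            "realized_sds": self.realized_sds,
            "realized_spearman": self.realized_spearman,
            "time_effect": self.time_effect,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# ----------------------------------------------------------------------


def default_config(
    seed: int = 0,
    n_patients: int = 20,
    missing_rate: float = 0.0,
    flat_time_effect: bool = False,
) -> SyntheticConfig:
    """Desk-scale default: platelet count plus the clot-firmness trio.

    Marginals are anchored to printed normal ranges (platelet count
    150-450 x10^9/L; derived platelet clot-firmness channel 35-45 mm; the
    fibrinogen channel chosen so the summed channel spans ~49-71 mm).
    Rank-correlation targets make the summed channel correlate strongly
    with platelet count while the hidden platelet channel stays weak
    (targets 0.78 / 0.067).

    Time-effect profiles are attribute-specific — platelet count dips
    hardest after bypass, the fibrinogen channel moderately, the platelet
    firmness channel not at all — so pooled ranks carry a real temporal
    signal that per-timepoint normalization visibly scrambles.
    """
    if flat_time_effect:
        effects = (("*", (1.0, 1.0, 1.0)),)
    else:
        effects = (
            ("PlatCt", (1.0, 0.45, 0.75)),
            ("MCF FIBTEM", (1.0, 0.6, 0.8)),
            ("MCF PLTEM", (1.0, 1.0, 1.0)),
        )
    return SyntheticConfig(
        n_patients=n_patients,
        attributes=(
            MarginalSpec(name="PlatCt", unit="10^9/L", normal_range=(150.0, 450.0)),
            MarginalSpec(name="MCF FIBTEM", unit="mm", normal_range=(9.0, 31.0)),
            MarginalSpec(name="MCF PLTEM", unit="mm", normal_range=(35.0, 45.0)),
        ),
        spearman_targets=(
            ("PlatCt", "MCF FIBTEM", 0.78),
            ("PlatCt", "MCF PLTEM", 0.067),
            ("MCF FIBTEM", "MCF PLTEM", 0.0),
        ),
        compose=(("MCF EXTEM", "mm", ("MCF FIBTEM", "MCF PLTEM")),),
        hidden=("MCF PLTEM",),
        time_effect=effects,
        missing_rate=missing_rate,
        seed=seed,
    )


def config_from_dict(d: Mapping, seed: int | None = None) -> SyntheticConfig:
    """Build a config from a plain (YAML-loaded) mapping."""
    attrs = []
    for a in d.get("attributes", []):
        rng_pair = a.get("normal_range")
        attrs.append(
            MarginalSpec(
                name=a["name"],
                unit=a.get("unit"),
                mean=a.get("mean"),
                sd=a.get("sd"),
                normal_range=tuple(rng_pair) if rng_pair else None,
                lower_bound=a.get("lower_bound", 0.0),
            )
        )
    targets = tuple((t[0], t[1], float(t[2])) for t in d.get("spearman_targets", []))
    compose = tuple(
        (c["name"], c.get("unit"), tuple(c["components"])) for c in d.get("compose", [])
    )
    effects = tuple((k, tuple(v)) for k, v in dict(d.get("time_effect", {})).items())
    return SyntheticConfig(
        n_patients=int(d.get("n_patients", 20)),
        timepoints=tuple(d.get("timepoints", ("S1", "S2", "S3"))),
        attributes=tuple(attrs),
        spearman_targets=targets,
        compose=compose,
        hidden=tuple(d.get("hidden", ())),
        time_effect=effects,
        missing_rate=float(d.get("missing_rate", 0.0)),
        seed=int(d.get("seed", 0) if seed is None else seed),
    )


# ----------------------------------------------------------------------


def spearman_to_latent(rho_s: float) -> float:
    """Latent Pearson correlation attaining Spearman ``rho_s`` under a
    Gaussian copula: ``2 sin(pi * rho_s / 6)``."""
    if abs(rho_s) > 1:
        raise ValueError(f"|rho_s| > 1: {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def nearest_psd(m: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest unit-diagonal PSD matrix."""
    m = np.asarray(m, dtype=float)
    w, v = np.linalg.eigh(m)
    if w.min() >= -eps:
        return m
    w = np.clip(w, 1e-12, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def build_latent_matrix(
    names: Sequence[str],
    targets: Sequence[tuple[str, str, float]],
) -> np.ndarray:
    """Latent correlation matrix from partial pairwise Spearman targets.

    Unspecified pairs default to 0. A non-PSD result is repaired to the
    nearest PSD correlation matrix with a warning.
    """
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    m = np.eye(k)
    for a, b, rho_s in targets:
        i, j = idx[a], idx[b]
        if i == j:
            continue
        r = spearman_to_latent(rho_s)
        m[i, j] = m[j, i] = r
    if np.linalg.eigvalsh(m).min() < -1e-10:
        warnings.warn("latent correlation matrix not PSD; applying nearest-PSD repair", UserWarning)
        m = nearest_psd(m)
    return m


def sample_copula(
    latent_matrix: np.ndarray,
    marginals: Sequence[MarginalSpec],
    n: int,
    seed: int | np.random.Generator = 0,
    mean_scales: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n`` correlated samples and push them through the marginals.

    ``mean_scales`` (n x k, optional) scales each cell's marginal mean —
    the hook used for the time-effect profile. Deterministic for a fixed
    integer seed.
    """
    latent_matrix = np.asarray(latent_matrix, dtype=float)
    k = latent_matrix.shape[0]
    if latent_matrix.shape != (k, k) or len(marginals) != k:
        raise ValueError("latent matrix and marginals disagree in dimension")
    if n < 1:
        raise ValueError("n must be >= 1")
    w, v = np.linalg.eigh(latent_matrix)
    if w.min() < -1e-8:
        raise ValueError("latent matrix is not PSD (beyond repair tolerance)")
    factor = v * np.sqrt(np.clip(w, 0.0, None))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, k)) @ factor.T
    u = stats.norm.cdf(z)

    out = np.empty((n, k))
    for j, marg in enumerate(marginals):
        if mean_scales is None:
            out[:, j] = marg.ppf(u[:, j])
        else:
            for scale in np.unique(mean_scales[:, j]):
                rows = mean_scales[:, j] == scale
                out[rows, j] = marg.ppf(u[rows, j], mean_scale=float(scale))
    return out


def inject_missing(table: LongTable, rate: float, seed: int) -> LongTable:
    """Independently drop each row with probability ``rate`` (seeded)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    keep = rng.random(len(table)) >= rate
    return LongTable(table.df[keep], timepoint_order=table.timepoint_order)


def generate_study(cfg: SyntheticConfig) -> tuple[LongTable, GeneratorReport]:
    """Generate one study table plus a report of realized statistics.

    Row count is ``n_patients x |timepoints| x |emitted attributes|``
    minus injected missingness. Samples at distinct (patient, timepoint)
    cells are independent copula draws; attributes within a cell are
    correlated per the config's Spearman targets.
    """
    if not cfg.attributes:
        raise ConfigError("config has no attributes")
    names = cfg.latent_names
    n_tp = len(cfg.timepoints)
    n = cfg.n_patients * n_tp

    latent = build_latent_matrix(names, cfg.spearman_targets)

    # sample layout: row index = patient-major, timepoint-minor
    tp_of_row = np.tile(np.arange(n_tp), cfg.n_patients)
    scales = np.empty((n, len(names)))
    for j, name in enumerate(names):
        profile = np.asarray(cfg.effect_profile(name))
        scales[:, j] = profile[tp_of_row]

    values = sample_copula(latent, cfg.attributes, n=n, seed=cfg.seed, mean_scales=scales)
    latent_cols = {name: values[:, j] for j, name in enumerate(names)}

    units = {m.name: m.unit for m in cfg.attributes}
    emitted: dict[str, np.ndarray] = {
        name: latent_cols[name] for name in names if name not in set(cfg.hidden)
    }
    for name, unit, parts in cfg.compose:
        emitted[name] = np.sum([latent_cols[p] for p in parts], axis=0)
        units[name] = unit

    pad = max(2, len(str(cfg.n_patients)))
    patients = [f"P{i + 1:0{pad}d}" for i in range(cfg.n_patients)]
    patient_of_row = np.repeat(np.arange(cfg.n_patients), n_tp)

    rows = []
    for attr in cfg.emitted_names:
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": [patients[i] for i in patient_of_row],
                    "timepoint": [cfg.timepoints[t] for t in tp_of_row],
                    "attribute": attr,
                    "value": emitted[attr],
                    "unit": units.get(attr),
                }
            )
        )
    long = pd.concat(rows, ignore_index=True)
    table = LongTable(long, timepoint_order=cfg.timepoints)
    if cfg.missing_rate > 0:
        table = inject_missing(table, cfg.missing_rate, seed=cfg.seed)

    # ground truth for the derived channel: same subtraction derive_pltem does
    truth_frames = []
    for name, _unit, parts in cfg.compose:
        if len(parts) != 2:
            continue
        keep_part = parts[0] if parts[0] not in set(cfg.hidden) else parts[1]
        derived_attr = name.replace("EXTEM", "PLTEM")
        truth_frames.append(
            pd.DataFrame(
                {
                    "patient_id": [patients[i] for i in patient_of_row],
                    "timepoint": [cfg.timepoints[t] for t in tp_of_row],
                    "attribute": derived_attr,
                    "value": emitted[name] - emitted[keep_part],
                }
            )
        )
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else None

    wide = pivot_wide(table)
    realized_rho: dict[str, float] = {}
    cols = list(wide.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) >= 2:
                realized_rho[f"{a} | {b}"] = spearman_rho(pair[a], pair[b])

    report = GeneratorReport(
        seed=cfg.seed,
        n_rows=len(table),
        realized_means={a: float(wide[a].mean()) for a in cols},
        realized_sds={a: float(wide[a].std(ddof=1)) for a in cols},
        realized_spearman=realized_rho,
        time_effect={name: list(cfg.effect_profile(name)) for name in cfg.emitted_names if name in names},
        derived_truth=truth,
    )
    return table, report
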