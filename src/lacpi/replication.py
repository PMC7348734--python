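"""Replicate agreement and variability statistics for co-located samplers.

Duplicate (field) or triplicate (laboratory) samplers deployed side-by-side
should report the same ΔPI; these functions quantify how closely they do:

* Pearson r and Spearman s between replicate vectors;
* coefficient of variation (CV, percent of |mean|, sample sd);
* RMSE relative to the replicate mean, pooled over replicate sets;
* agreement tables grouped overall, by sampling date, or by quintile of the
  pair-mean ΔPI;
* a three-way CV decomposition: variability among locations at a time-point,
  within a location over time, and between replicates at the same
  location-time — the ordering among > within > replicate is what makes the
  method able to rank locations by long-term exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "ReplicateSet",
    "AgreementTable",
    "VariabilityDecomposition",
    "pearson_r",
    "spearman_s",
    "cv_replicates",
    "rmse_vs_replicate_mean",
    "agreement_by_group",
    "variability_decomposition",
]


@dataclass
class ReplicateSet:
    """ΔPI values of co-located samplers at one location and time-point."""

    location_id: str
    time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise InputError("a replicate set needs at least 2 values")


def _as_vectors(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise InputError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation."""
    x, y = _as_vectors(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman_s(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties receive average ranks)."""
    x, y = _as_vectors(x, y)
    return float(stats.spearmanr(x, y).statistic)


def cv_replicates(replicates: ReplicateSet) -> float:
    """Coefficient of variation, percent, absolute value: sample sd (n−1
    denominator) over |mean|."""
    mean = replicates.values.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined: replicate mean is 0")
    sd = replicates.values.std(ddof=1)
    return float(sd / abs(mean) * 100.0)


def rmse_vs_replicate_mean(
    sets: Iterable[ReplicateSet],
) -> tuple[float, float]:
    """RMSE of replicates about their set mean, pooled over all sets.

    Deviations ``value − set_mean`` are pooled over every replicate of every
    set; the second return value is RMSE over the absolute grand mean of all
    ΔPI values, in percent.  For a single pair the RMSE equals half the
    absolute difference.
    """
    sets = list(sets)
    if not sets:
        raise InputError("no replicate sets given")
    deviations = []
    all_values = []
    for s in sets:
        deviations.append(s.values - s.values.mean())
        all_values.append(s.values)
    pooled = np.concatenate(deviations)
    values = np.concatenate(all_values)
    rmse = float(np.sqrt(np.mean(pooled**2)))
    grand_mean = values.mean()
    if grand_mean == 0:
        raise UndefinedStatisticError("RMSE/mean undefined: grand mean is 0")
    return rmse, float(rmse / abs(grand_mean) * 100.0)


@dataclass(frozen=True)
class AgreementTable:
    """Agreement statistics for one group of paired samplers."""

    label: str
    n_pairs: int
    mean_delta: float  # mean of all ΔPI values in the group (both samplers)
    pearson: float  # NaN when undefined (zero variance)
    spearman: float
    rmse: float
    rmse_over_mean: float  # percent, absolute


def agreement_by_group(
    pairs: pd.DataFrame,
    grouping: str = "all",
    n_quantile_groups: int = 5,
    min_pairs: int = 3,
) -> tuple[list[AgreementTable], list[str]]:
    """Paired-sampler agreement, grouped ``all`` | ``by_date`` | ``by_quintile``.

    ``pairs`` needs columns ``location_id, date, delta_a, delta_b``.  Quantile
    groups are formed by ranking the pooled pair-mean ΔPI values (least
    darkening first) and splitting into ``n_quantile_groups`` equal-count
    groups, ties broken by stable order of ``location_id``.  Groups smaller
    than ``min_pairs`` are skipped and reported in the returned warning list.
    Correlations of zero-variance groups are reported as NaN.
    """
    required = {"location_id", "date", "delta_a", "delta_b"}
    if not required.issubset(pairs.columns):
        raise InputError(f"pairs table needs columns {sorted(required)}")
    if len(pairs) == 0:
        raise InputError("empty pairs table")

    if grouping == "all":
        groups = [("all", pairs)]
    elif grouping == "by_date":
        groups = [(str(d), g) for d, g in pairs.groupby("date", sort=True)]
    elif grouping == "by_quintile":
        df = pairs.copy()
        df["_pair_mean"] = (df["delta_a"] + df["delta_b"]) / 2.0
        # least darkening (closest to white, most positive) first → Q1
        df = df.sort_values(
            ["_pair_mean", "location_id"], ascending=[False, True], kind="stable"
        )
        chunks = np.array_split(np.arange(len(df)), n_quantile_groups)
        groups = [
            (f"Q{i + 1}", df.iloc[idx]) for i, idx in enumerate(chunks) if len(idx)
        ]
    else:
        raise InputError(f"unknown grouping {grouping!r}")

    tables: list[AgreementTable] = []
    skipped: list[str] = []
    for label, g in groups:
        if len(g) < min_pairs:
            skipped.append(f"group {label!r} skipped: only {len(g)} pairs")
            continue
        a = g["delta_a"].to_numpy(dtype=float)
        b = g["delta_b"].to_numpy(dtype=float)
        try:
            r = pearson_r(a, b)
            s = spearman_s(a, b)
        except UndefinedStatisticError:
            r = s = float("nan")
        sets = [
            ReplicateSet(str(row.location_id), 0.0, np.array([row.delta_a, row.delta_b]))
            for row in g.itertuples()
        ]
        rmse, rel = rmse_vs_replicate_mean(sets)
        tables.append(
            AgreementTable(
                label=label,
                n_pairs=len(g),
                mean_delta=float(np.concatenate([a, b]).mean()),
                pearson=r,
                spearman=s,
                rmse=rmse,
                rmse_over_mean=rel,
            )
        )
    return tables, skipped


@dataclass(frozen=True)
class VariabilityDecomposition:
    """Unweighted mean CVs: among locations, within location, replicates."""

    among_locations_cv: float  # per date: CV across location means, averaged
    within_location_cv: float  # per location: CV across its per-date means
    replicate_cv: float  # per location-date: CV across replicates, averaged
    n_locations: int
    n_dates: int


def variability_decomposition(records: pd.DataFrame) -> VariabilityDecomposition:
    """Three-way CV decomposition of a campaign's ΔPI records.

    ``records`` needs columns ``location_id, time, delta_pi`` with at least 2
    locations, 2 time-points and 2 replicates per location-time.  Each CV is
    computed per group (sample sd over |mean|, percent) and then averaged
    without weighting.
    """
    required = {"location_id", "time", "delta_pi"}
    if not required.issubset(records.columns):
        raise InputError(f"records table needs columns {sorted(required)}")
    n_loc = records["location_id"].nunique()
    n_dates = records["time"].nunique()
    if n_loc < 2 or n_dates < 2:
        raise InputError("need at least 2 locations and 2 time-points")
    counts = records.groupby(["location_id", "time"]).size()
    if counts.min() < 2:
        raise InputError("need at least 2 replicates per location-time")

    def _cv(values: np.ndarray) -> float:
        mean = values.mean()
        if mean == 0:
            raise UndefinedStatisticError("CV undefined: group mean is 0")
        return float(values.std(ddof=1) / abs(mean) * 100.0)

    loc_means = (
        records.groupby(["time", "location_id"])["delta_pi"].mean().rename("mean")
    )
    among = np.mean(
        [_cv(g.to_numpy()) for _, g in loc_means.groupby(level="time")]
    )
    within = np.mean(
        [_cv(g.to_numpy()) for _, g in loc_means.groupby(level="location_id")]
    )
    repl = np.mean(
        [
            _cv(g["delta_pi"].to_numpy())
            for _, g in records.groupby(["location_id", "time"])
        ]
    )
    return VariabilityDecomposition(
        among_locations_cv=float(among),
        within_location_cv=float(within),
        replicate_cv=float(repl),
        n_locations=int(n_loc),
        n_dates=int(n_dates),
    )
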