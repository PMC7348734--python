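"""Per-sampler darkening time series: rates, fits, detection limits, saturation.

A :class:`DeltaSeries` holds one sampler's ΔPI at each sampling time, starting
at its own baseline (ΔPI = 0).  Field campaigns use days; laboratory chamber
runs use minutes — the unit is carried on the series and never converted
silently.

The cohort-level operations implement the analyses run on such series:

* interval and whole-period darkening rates (PI per unit time);
* ordinary least squares of ΔPI on exposure time with R²;
* the lower limit of detection: the earliest sampling time at which *every*
  sampler shows a measurable (default 1% of full scale) change;
* the upper limit via the replacement-sampler probe: if samplers exposed
  since baseline stop darkening over a window while a freshly deployed
  sampler at the same location darkens strongly, the original surfaces have
  saturated;
* median/IQR summaries of per-sampler rates within a sampling period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError, RangeError, WindowError

__all__ = [
    "DeltaSeries",
    "LinearFit",
    "RateTable",
    "SaturationAssessment",
    "PeriodRateSummary",
    "interval_rates",
    "fit_linear_darkening",
    "lower_lod_time",
    "assess_saturation",
    "period_rate_summary",
]


@dataclass
class DeltaSeries:
    """Ordered (exposure_time, ΔPI) points for one sampler.

    Times are strictly increasing and the first point is the sampler's own
    baseline (ΔPI exactly 0).  Samplers present since the campaign start
    (``role="original"``) have their baseline at time 0; a replacement
    sampler's baseline is its deployment time on the shared campaign clock.
    """

    sampler_id: str
    location_id: str
    times: np.ndarray
    deltas: np.ndarray
    role: str = "original"
    time_unit: str = "day"
    max_value: int = 4095

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.times.shape != self.deltas.shape or self.times.ndim != 1:
            raise InputError("times and deltas must be 1-D arrays of equal length")
        if len(self.times) < 1:
            raise InputError("series must contain at least the baseline point")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("exposure times must be strictly increasing")
        if self.deltas[0] != 0.0:
            raise InputError("first point of a series must be the baseline (ΔPI = 0)")
        if self.role == "original" and self.times[0] != 0.0:
            raise InputError("original samplers must have their baseline at time 0")
        if self.role not in ("original", "replacement"):
            raise InputError(f"role must be 'original' or 'replacement': {self.role!r}")

    def __len__(self) -> int:
        return len(self.times)

    def value_at(self, t: float, atol: float = 1e-9) -> float:
        """ΔPI at an observed sampling time (no interpolation)."""
        hits = np.nonzero(np.isclose(self.times, t, rtol=0.0, atol=atol))[0]
        if len(hits) == 0:
            raise WindowError(
                f"sampler {self.sampler_id!r} has no observation at t={t}"
            )
        return float(self.deltas[hits[0]])

    def observed_at(self, t: float, atol: float = 1e-9) -> bool:
        return bool(np.any(np.isclose(self.times, t, rtol=0.0, atol=atol)))


@dataclass(frozen=True)
class RateTable:
    """Interval darkening rates plus the whole-period rate, PI per unit time."""

    intervals: tuple[tuple[float, float], ...]
    rates: tuple[float, ...]
    whole_period: float
    time_unit: str = "day"


def interval_rates(series: DeltaSeries) -> RateTable:
    """Rate over each consecutive sampling interval and over the whole period.

    ``rate_i = (ΔPI_{i+1} − ΔPI_i) / (t_{i+1} − t_i)``; the whole-period rate
    is the secant from first to last point.  Negative rates mean darkening.
    """
    if len(series) < 2:
        raise InputError("need at least 2 points to compute rates")
    dt = np.diff(series.times)
    rates = np.diff(series.deltas) / dt
    whole = (series.deltas[-1] - series.deltas[0]) / (series.times[-1] - series.times[0])
    ivals = tuple(
        (float(a), float(b)) for a, b in zip(series.times[:-1], series.times[1:])
    )
    return RateTable(
        intervals=ivals,
        rates=tuple(float(r) for r in rates),
        whole_period=float(whole),
        time_unit=series.time_unit,
    )


@dataclass(frozen=True)
class LinearFit:
    """OLS of ΔPI on exposure time."""

    slope: float  # PI per unit time
    intercept: float  # PI
    r_squared: float
    n_points: int
    slope_stderr: float


def fit_linear_darkening(series: DeltaSeries) -> LinearFit:
    """Ordinary least squares of ΔPI on exposure time; R² is the coefficient
    of determination.  Requires at least 3 points."""
    if len(series) < 3:
        raise InputError("need at least 3 points for a linear fit")
    res = stats.linregress(series.times, series.deltas)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(series),
        slope_stderr=float(res.stderr),
    )


def lower_lod_time(
    cohort: Sequence[DeltaSeries],
    threshold_percent: float = 1.0,
    max_value: int = 4095,
) -> float | None:
    """Earliest sampling time at which every observed sampler shows a
    measurable change (|ΔPI| ≥ ``threshold_percent`` of full scale).

    Only samplers with an observation at a given time participate at that
    time.  Returns ``None`` if no sampling time qualifies ("not reached").
    With ``threshold_percent = 0`` any nonzero change qualifies.
    """
    if len(cohort) == 0:
        raise InputError("empty cohort")
    if threshold_percent < 0:
        raise RangeError("threshold_percent must be >= 0")
    threshold_pi = threshold_percent / 100.0 * max_value
    all_times = np.unique(np.concatenate([s.times for s in cohort]))
    for t in all_times[all_times > np.min([s.times[0] for s in cohort])]:
        observed = [s for s in cohort if s.observed_at(t)]
        if not observed:
            continue
        values = np.array([s.value_at(t) for s in observed])
        ok = (
            np.all(np.abs(values) > 0.0)
            if threshold_pi == 0.0
            else np.all(np.abs(values) >= threshold_pi)
        )
        if ok:
            return float(t)
    return None


@dataclass(frozen=True)
class SaturationAssessment:
    """Outcome of the replacement-sampler saturation probe over one window."""

    location_id: str
    window: tuple[float, float]
    continuing_change: float  # mean over continuing samplers of ΔPI(t1) − ΔPI(t0)
    replacement_change: float
    ratio: float  # |replacement| / max(|continuing|, eps)
    saturated: bool


def assess_saturation(
    continuing: Sequence[DeltaSeries],
    replacement: DeltaSeries,
    window: tuple[float, float],
    ratio_threshold: float = 10.0,
    continuing_tolerance: float = 41.0,
    measurable_threshold: float = 41.0,
    eps: float = 1.0,
) -> SaturationAssessment:
    """Replacement-sampler rule for surface saturation.

    Saturated iff, over the window, the continuing (long-exposed) samplers'
    mean change stays within ``continuing_tolerance`` (default 41 PI, the 1%
    measurable-change threshold) while the freshly deployed replacement
    changes by at least ``measurable_threshold`` and by at least
    ``ratio_threshold`` times the continuing change (denominator floored at
    ``eps`` to keep the ratio finite when continuing samplers are flat).
    All three quantities are reported regardless of the verdict.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise WindowError(f"window must be increasing, got {window}")
    if len(continuing) == 0:
        raise InputError("need at least one continuing series")
    if abs(replacement.value_at(t0)) > 1e-9:
        raise WindowError(
            "replacement series must start at ΔPI = 0 at the window start"
        )
    cont_changes = [s.value_at(t1) - s.value_at(t0) for s in continuing]
    continuing_change = float(np.mean(cont_changes))
    replacement_change = float(replacement.value_at(t1) - replacement.value_at(t0))
    ratio = abs(replacement_change) / max(abs(continuing_change), eps)
    saturated = (
        abs(continuing_change) <= continuing_tolerance
        and abs(replacement_change) >= measurable_threshold
        and ratio >= ratio_threshold
    )
    return SaturationAssessment(
        location_id=replacement.location_id,
        window=(t0, t1),
        continuing_change=continuing_change,
        replacement_change=replacement_change,
        ratio=float(ratio),
        saturated=bool(saturated),
    )


@dataclass(frozen=True)
class PeriodRateSummary:
    """Median and IQR of per-sampler rates within one sampling period."""

    period: tuple[float, float]
    median: float
    iqr: tuple[float, float]  # (25th, 75th percentile), linear interpolation
    rates: tuple[float, ...]
    n_samplers: int
    time_unit: str = "day"


def period_rate_summary(
    cohort: Sequence[DeltaSeries], period: tuple[float, float]
) -> PeriodRateSummary:
    """Per-sampler secant rate over ``period`` for every sampler observed at
    both endpoints, summarized as median and interquartile range."""
    t0, t1 = float(period[0]), float(period[1])
    if t1 <= t0:
        raise InputError(f"period must be increasing, got {period}")
    if len(cohort) == 0:
        raise InputError("empty cohort")
    rates = []
    for s in cohort:
        if s.observed_at(t0) and s.observed_at(t1):
            rates.append((s.value_at(t1) - s.value_at(t0)) / (t1 - t0))
    if not rates:
        raise InputError(f"no sampler covers the period {period}")
    arr = np.array(rates)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return PeriodRateSummary(
        period=(t0, t1),
        median=float(med),
        iqr=(float(q25), float(q75)),
        rates=tuple(float(r) for r in arr),
        n_samplers=len(arr),
        time_unit=cohort[0].time_unit,
    )
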