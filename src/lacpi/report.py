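"""Campaign reports: rates, fits, detection limits, agreement, plots.

Everything here renders the analysis tables a campaign report needs from a
full-precision ΔPI table.  CSV outputs carry full precision; rounding is a
presentation concern left to whoever reads them.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LacpiError
from .pipeline import build_series
from .replication import (
    agreement_by_group,
    variability_decomposition,
)
from .series import (
    DeltaSeries,
    assess_saturation,
    fit_linear_darkening,
    interval_rates,
    lower_lod_time,
    period_rate_summary,
)

__all__ = [
    "rates_table",
    "fits_table",
    "lod_summary",
    "saturation_summary",
    "pairs_from_deltas",
    "agreement_tables",
    "variability_summary",
    "plot_darkening_curves",
    "write_report",
]


def rates_table(cohort: Sequence[DeltaSeries]) -> pd.DataFrame:
    """Per-sampler interval rates plus a whole-period row each."""
    rows = []
    for s in cohort:
        if len(s) < 2:
            continue
        table = interval_rates(s)
        for (t0, t1), rate in zip(table.intervals, table.rates):
            rows.append(
                {
                    "sampler_id": s.sampler_id,
                    "location_id": s.location_id,
                    "interval_start": t0,
                    "interval_end": t1,
                    "rate_pi_per_unit": rate,
                    "whole_period": False,
                    "time_unit": s.time_unit,
                }
            )
        rows.append(
            {
                "sampler_id": s.sampler_id,
                "location_id": s.location_id,
                "interval_start": s.times[0],
                "interval_end": s.times[-1],
                "rate_pi_per_unit": table.whole_period,
                "whole_period": True,
                "time_unit": s.time_unit,
            }
        )
    return pd.DataFrame(rows)


def fits_table(cohort: Sequence[DeltaSeries]) -> pd.DataFrame:
    """OLS darkening fit per sampler (samplers with ≥ 3 points)."""
    rows = []
    for s in cohort:
        if len(s) < 3:
            continue
        fit = fit_linear_darkening(s)
        rows.append(
            {
                "sampler_id": s.sampler_id,
                "location_id": s.location_id,
                "slope_pi_per_unit": fit.slope,
                "intercept_pi": fit.intercept,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def lod_summary(
    cohort: Sequence[DeltaSeries], threshold_percent: float = 1.0
) -> dict:
    """Lower limit of detection over samplers present since baseline."""
    originals = [s for s in cohort if s.role == "original"]
    if not originals:
        raise InputError("no baseline-deployed samplers in cohort")
    t = lower_lod_time(originals, threshold_percent=threshold_percent,
                       max_value=originals[0].max_value)
    return {
        "threshold_percent": threshold_percent,
        "n_samplers": len(originals),
        "lower_lod_time": t,
        "reached": t is not None,
        "time_unit": originals[0].time_unit,
    }


def saturation_summary(
    cohort: Sequence[DeltaSeries],
    ratio_threshold: float = 10.0,
    continuing_tolerance: float = 41.0,
) -> dict | None:
    """Replacement-sampler probe over the replacement's first interval, if a
    replacement sampler is present; otherwise ``None``."""
    replacements = [s for s in cohort if s.role == "replacement"]
    if not replacements:
        return None
    repl = replacements[0]
    if len(repl) < 2:
        return None
    window = (float(repl.times[0]), float(repl.times[1]))
    continuing = [
        s
        for s in cohort
        if s.role == "original"
        and s.location_id == repl.location_id
        and s.observed_at(window[0])
        and s.observed_at(window[1])
    ]
    if not continuing:
        return None
    result = assess_saturation(
        continuing,
        repl,
        window,
        ratio_threshold=ratio_threshold,
        continuing_tolerance=continuing_tolerance,
    )
    return asdict(result)


def pairs_from_deltas(deltas: pd.DataFrame) -> pd.DataFrame:
    """Duplicate-sampler pairs (location_id, date, delta_a, delta_b) per
    post-baseline time, from the first two baseline-deployed samplers at
    each location (by sampler id)."""
    rows = []
    post = deltas[(deltas["role"] == "original") & (deltas["exposure_time"] > 0)]
    for (loc, t), g in post.groupby(["location_id", "time"], sort=True):
        g = g.sort_values("sampler_id")
        if len(g) < 2:
            continue
        rows.append(
            {
                "location_id": loc,
                "date": float(t),
                "delta_a": float(g["delta_pi"].iloc[0]),
                "delta_b": float(g["delta_pi"].iloc[1]),
            }
        )
    return pd.DataFrame(rows)


def agreement_tables(pairs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Agreement statistics overall, by date and by quintile as DataFrames."""
    out = {}
    for grouping in ("all", "by_date", "by_quintile"):
        tables, skipped = agreement_by_group(pairs, grouping=grouping)
        df = pd.DataFrame([asdict(t) for t in tables])
        df.attrs["skipped"] = skipped
        out[grouping] = df
    return out


def variability_summary(deltas: pd.DataFrame) -> dict:
    """Three-way CV decomposition of post-baseline replicate records; marked
    not-available when the campaign lacks the needed structure."""
    post = deltas[(deltas["role"] == "original") & (deltas["exposure_time"] > 0)]
    records = post[["location_id", "time", "delta_pi"]]
    try:
        decomp = variability_decomposition(records)
        return {"available": True, **asdict(decomp)}
    except LacpiError as exc:
        return {"available": False, "reason": str(exc)}


def plot_darkening_curves(
    cohort: Sequence[DeltaSeries], path: str | Path, title: str = ""
) -> None:
    """One overview figure: ΔPI versus time, one line per location (mean of
    the location's samplers at each common time)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    by_location: dict[str, list[DeltaSeries]] = {}
    for s in cohort:
        if s.role == "original":
            by_location.setdefault(s.location_id, []).append(s)
    for loc, group in sorted(by_location.items()):
        times = group[0].times
        mean = np.mean([s.deltas for s in group], axis=0)
        ax.plot(times, mean, marker="o", markersize=3, linewidth=1, label=loc)
    unit = cohort[0].time_unit if cohort else "day"
    ax.set_xlabel(f"exposure time [{unit}]")
    ax.set_ylabel("change in reflectance ΔPI [PI]")
    ax.axhline(0.0, color="k", linewidth=0.5)
    if title:
        ax.set_title(title)
    if len(by_location) <= 20:
        ax.legend(fontsize=5, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report(
    deltas: pd.DataFrame,
    out_dir: str | Path,
    threshold_percent: float = 1.0,
    ratio_threshold: float = 10.0,
    continuing_tolerance: float = 41.0,
    time_unit: str = "day",
    plots: bool = True,
) -> dict:
    """Write the full report bundle for a measured campaign.

    Emits ``rates.csv``, ``fits.csv``, ``lod.json``, ``saturation.json``
    (when a replacement sampler exists), agreement CSVs, and
    ``variability.json``; optionally a darkening-curve overview plot.
    Returns the summary dictionaries for programmatic use.
    """
    if len(deltas) == 0:
        raise InputError("empty ΔPI table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = build_series(deltas, time_unit=time_unit)

    rates_table(cohort).to_csv(out / "rates.csv", index=False)
    fits_table(cohort).to_csv(out / "fits.csv", index=False)

    lod = lod_summary(cohort, threshold_percent=threshold_percent)
    (out / "lod.json").write_text(json.dumps(lod, indent=2))

    saturation = saturation_summary(
        cohort,
        ratio_threshold=ratio_threshold,
        continuing_tolerance=continuing_tolerance,
    )
    if saturation is not None:
        (out / "saturation.json").write_text(json.dumps(saturation, indent=2))

    pairs = pairs_from_deltas(deltas)
    agreement = {}
    if len(pairs) >= 3:
        agreement = agreement_tables(pairs)
        for grouping, df in agreement.items():
            df.to_csv(out / f"agreement_{grouping}.csv", index=False)

    variability = variability_summary(deltas)
    (out / "variability.json").write_text(json.dumps(variability, indent=2))

    if plots:
        plot_darkening_curves(cohort, out / "darkening_curves.png")

    return {
        "lod": lod,
        "saturation": saturation,
        "variability": variability,
        "n_samplers": len(cohort),
        "n_pairs": int(len(pairs)),
    }
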