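"""Campaign measurement: image sessions → intensity table → ΔPI records → series.

Glue between the imaging, reflectance and series layers.  A campaign is a set
of session stacks (one photograph per sampler per sampling time, each holding
the sampler surface and the unexposed reference), a layout file mapping named
surfaces to ROIs, and a manifest mapping session files to sampler, location,
role and sampling time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import InputError, PairingError
from .imaging import (
    FrameStack,
    SurfaceLayout,
    extract_roi_mean,
    qc_frames,
    read_frame_stack,
)
from .reflectance import IntensitySummary, delta_pi
from .series import DeltaSeries

__all__ = [
    "MeasureResult",
    "intensities_from_sessions",
    "deltas_from_intensities",
    "measure_directory",
    "build_series",
]

MANIFEST_COLUMNS = ("session_id", "sampler_id", "location_id", "role", "time")


@dataclass
class MeasureResult:
    """Output of measuring a campaign: full-precision tables."""

    deltas: pd.DataFrame  # one row per sampler per post-baseline time
    intensities: pd.DataFrame  # one row per session
    qc: pd.DataFrame  # one row per frame per session


def intensities_from_sessions(
    sessions: Iterable[tuple[FrameStack, dict]],
    layout: SurfaceLayout,
    sample_surface: str | None = None,
    saturation_fraction_limit: float = 0.01,
    expected_frames: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean sample/reference PI per session plus pooled per-frame QC.

    Each ``meta`` dict must carry the manifest columns; ``surface`` may name
    which layout sample entry the sampler occupies (defaults to the sole
    sample entry).
    """
    if sample_surface is None and len(layout.samples) == 1:
        sample_surface = layout.samples[0].name
    intensity_rows = []
    qc_rows = []
    for stack, meta in sessions:
        missing = [c for c in MANIFEST_COLUMNS if c not in meta]
        if missing:
            raise InputError(f"session metadata missing columns {missing}")
        surface = meta.get("surface", sample_surface)
        if surface is None:
            raise InputError(
                "layout has multiple sample surfaces; manifest must name one "
                "per session in a 'surface' column"
            )
        pi_sample = extract_roi_mean(stack, layout.entry(surface))
        pi_reference = extract_roi_mean(stack, layout.reference)
        intensity_rows.append(
            {
                "session_id": meta["session_id"],
                "sampler_id": meta["sampler_id"],
                "location_id": meta["location_id"],
                "role": meta["role"],
                "time": float(meta["time"]),
                "pi_sample": pi_sample,
                "pi_reference": pi_reference,
                "n_frames": stack.n_frames,
                "max_value": stack.max_value,
            }
        )
        report = qc_frames(
            stack,
            layout,
            saturation_fraction_limit=saturation_fraction_limit,
            expected_frames=expected_frames,
        )
        frame_table = report.frame_table.copy()
        frame_table.insert(0, "session_id", meta["session_id"])
        frame_table["frame_count_mismatch"] = report.frame_count_mismatch
        qc_rows.append(frame_table)
    if not intensity_rows:
        raise InputError("no sessions to measure")
    return pd.DataFrame(intensity_rows), pd.concat(qc_rows, ignore_index=True)


def deltas_from_intensities(intensities: pd.DataFrame) -> pd.DataFrame:
    """ΔPI of every session against its sampler's baseline session.

    The baseline is the sampler's earliest session: time 0 for samplers
    present since the campaign start, the deployment time for a replacement.
    An original sampler without a time-0 session is a fatal pairing error.
    """
    rows = []
    for sampler_id, group in intensities.groupby("sampler_id", sort=True):
        group = group.sort_values("time")
        base = group.iloc[0]
        if base["role"] == "original" and base["time"] != 0.0:
            raise PairingError(
                f"sampler {sampler_id!r} has no baseline (time 0) session; "
                f"earliest is t={base['time']}"
            )
        max_value = int(base["max_value"])
        sample_0 = IntensitySummary(
            str(sampler_id), "sample", base["time"], base["pi_sample"],
            int(base["n_frames"]), max_value,
        )
        ref_0 = IntensitySummary(
            "reference", "reference", base["time"], base["pi_reference"],
            int(base["n_frames"]), max_value,
        )
        for row in group.itertuples():
            sample_t = IntensitySummary(
                str(sampler_id), "sample", row.time, row.pi_sample,
                int(row.n_frames), max_value,
            )
            ref_t = IntensitySummary(
                "reference", "reference", row.time, row.pi_reference,
                int(row.n_frames), max_value,
            )
            rec = delta_pi(
                sample_0, ref_0, sample_t, ref_t,
                sampler_id=str(sampler_id),
                location_id=str(row.location_id),
            )
            rows.append(
                {
                    "sampler_id": rec.sampler_id,
                    "location_id": rec.location_id,
                    "role": row.role,
                    "time": float(row.time),
                    "exposure_time": rec.exposure_time,
                    "pi_sample": row.pi_sample,
                    "pi_reference": row.pi_reference,
                    "delta_pi": rec.delta_pi,
                    "delta_percent": rec.delta_percent,
                    "max_value": max_value,
                }
            )
    return pd.DataFrame(rows)


def measure_directory(
    campaign_dir: str | Path,
    layout_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
    expected_bit_depth: int = 12,
    expected_frames: int | None = None,
) -> MeasureResult:
    """Measure a campaign directory written by ``generate_campaign`` (or laid
    out the same way): ``layout.yaml``, ``manifest.csv`` and session TIFFs."""
    root = Path(campaign_dir)
    layout = SurfaceLayout.from_yaml(layout_path or root / "layout.yaml")
    manifest = pd.read_csv(manifest_path or root / "manifest.csv")
    missing = [c for c in MANIFEST_COLUMNS + ("session_file",) if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest missing columns {missing}")

    def _sessions():
        for row in manifest.itertuples():
            stack = read_frame_stack(
                root / row.session_file,
                expected_bit_depth=expected_bit_depth,
                session_id=str(row.session_id),
            )
            yield stack, {c: getattr(row, c) for c in MANIFEST_COLUMNS}

    intensities, qc = intensities_from_sessions(
        _sessions(), layout, expected_frames=expected_frames
    )
    deltas = deltas_from_intensities(intensities)
    return MeasureResult(deltas=deltas, intensities=intensities, qc=qc)


def build_series(
    deltas: pd.DataFrame, time_unit: str = "day"
) -> list[DeltaSeries]:
    """Assemble one :class:`DeltaSeries` per sampler from a ΔPI table."""
    series = []
    for sampler_id, group in deltas.groupby("sampler_id", sort=True):
        group = group.sort_values("time")
        series.append(
            DeltaSeries(
                sampler_id=str(sampler_id),
                location_id=str(group["location_id"].iloc[0]),
                times=group["time"].to_numpy(dtype=float),
                deltas=group["delta_pi"].to_numpy(dtype=float),
                role=str(group["role"].iloc[0]),
                time_unit=time_unit,
                max_value=int(group["max_value"].iloc[0]),
            )
        )
    return series
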