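"""The change-in-reflectance metric ΔPI with double-reference correction.

A passively exposed white filter darkens as light-absorbing carbon deposits on
it.  Its reflectance at a time-point is summarized as the mean pixel intensity
(PI) of its ROI; the change since baseline is computed against an unexposed
reference surface photographed in the same session:

    ΔPI[T−0] = (PI_sample,T − PI_ref,T) − (PI_sample,0 − PI_ref,0)

Subtracting the sampler's own baseline removes filter-to-filter differences in
initial whiteness; subtracting the session reference removes session-to-session
differences in overall lightbox brightness (an additive lighting shift cancels
exactly; a multiplicative gain shift does not — see docs/methods.md).
Darkening is negative; −max_value (−100%) is white-to-black.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PairingError, RangeError, ScaleError

__all__ = [
    "IntensitySummary",
    "DeltaRecord",
    "delta_pi",
    "pi_to_percent",
    "percent_to_pi",
    "is_measurable_change",
]


@dataclass(frozen=True)
class IntensitySummary:
    """Mean PI of one surface's ROI at one time-point."""

    surface_id: str
    role: str  # "sample" | "reference"
    t: float  # exposure time (days in the field, minutes in the lab)
    mean_pi: float
    n_frames: int
    max_value: int = 4095

    def __post_init__(self) -> None:
        if self.role not in ("sample", "reference"):
            raise PairingError(f"role must be 'sample' or 'reference': {self.role!r}")
        if not 0.0 <= self.mean_pi <= self.max_value:
            raise RangeError(
                f"mean_pi {self.mean_pi} outside [0, {self.max_value}]"
            )
        if self.t < 0:
            raise RangeError(f"exposure time must be >= 0, got {self.t}")


@dataclass(frozen=True)
class DeltaRecord:
    """ΔPI of one sampler over [baseline, T]; ``delta_percent`` is of full scale."""

    sampler_id: str
    location_id: str
    exposure_time: float
    delta_pi: float
    delta_percent: float
    max_value: int = 4095


def delta_pi(
    sample_baseline: IntensitySummary,
    reference_baseline: IntensitySummary,
    sample_at_t: IntensitySummary,
    reference_at_t: IntensitySummary,
    sampler_id: str | None = None,
    location_id: str = "",
) -> DeltaRecord:
    """Double-difference change in reflectance between baseline and time T.

    The two baseline summaries must share a time, as must the two at-T
    summaries; roles must match sample/sample and reference/reference; all
    four must share ``max_value``.
    """
    if sample_baseline.role != "sample" or sample_at_t.role != "sample":
        raise PairingError("sample summaries must have role 'sample'")
    if reference_baseline.role != "reference" or reference_at_t.role != "reference":
        raise PairingError("reference summaries must have role 'reference'")
    if sample_baseline.t != reference_baseline.t:
        raise PairingError(
            f"baseline times differ: sample t={sample_baseline.t}, "
            f"reference t={reference_baseline.t}"
        )
    if sample_at_t.t != reference_at_t.t:
        raise PairingError(
            f"follow-up times differ: sample t={sample_at_t.t}, "
            f"reference t={reference_at_t.t}"
        )
    max_values = {
        s.max_value
        for s in (sample_baseline, reference_baseline, sample_at_t, reference_at_t)
    }
    if len(max_values) != 1:
        raise ScaleError(f"summaries mix full-scale values: {sorted(max_values)}")
    max_value = max_values.pop()

    value = (sample_at_t.mean_pi - reference_at_t.mean_pi) - (
        sample_baseline.mean_pi - reference_baseline.mean_pi
    )
    return DeltaRecord(
        sampler_id=sampler_id if sampler_id is not None else sample_at_t.surface_id,
        location_id=location_id,
        exposure_time=sample_at_t.t - sample_baseline.t,
        delta_pi=value,
        delta_percent=pi_to_percent(value, max_value),
        max_value=max_value,
    )


def pi_to_percent(delta_pi: float, max_value: int = 4095) -> float:
    """Express a ΔPI in percent of full scale (−41 PI → −1.001% at 12 bit)."""
    if abs(delta_pi) > max_value:
        raise RangeError(f"|delta_pi| = {abs(delta_pi)} exceeds full scale {max_value}")
    return delta_pi / max_value * 100.0


def percent_to_pi(percent: float, max_value: int = 4095) -> float:
    """Inverse of :func:`pi_to_percent` (exact up to floating point)."""
    if abs(percent) > 100.0:
        raise RangeError(f"|percent| = {abs(percent)} exceeds 100")
    return percent / 100.0 * max_value


def is_measurable_change(
    delta_pi: float, threshold_percent: float = 1.0, max_value: int = 4095
) -> bool:
    """True iff |ΔPI| reaches ``threshold_percent`` of full scale.

    At 12 bit the default 1% threshold is 40.95 PI, so a change of −41 PI is
    measurable and −40 PI is not.
    """
    if threshold_percent <= 0:
        raise RangeError("threshold_percent must be > 0")
    return abs(delta_pi) >= threshold_percent / 100.0 * max_value
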