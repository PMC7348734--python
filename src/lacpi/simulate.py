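"""Synthetic lightbox: campaigns of darkening filter images with known truth.

No field images are distributed with this package, so every pipeline stage is
validated against simulated sessions that carry the statistical structure the
measurement assumes:

* a white filter surface (baseline PI near full scale) darkening monotonically
  with cumulative dose along a saturating exponential,
  ``PI(t) = pi_sat + (pi_0 − pi_sat)·exp(−k·D(t))`` with dose
  ``D(t) = v_d·C·t`` (deposition velocity × concentration × time; arbitrary
  consistent units — no calibration to mass concentration is claimed);
* a session-level additive lighting offset and multiplicative gain shared by
  all surfaces in a photograph (what the double-reference ΔPI is built to
  remove);
* per-frame multiplicative flicker and per-pixel additive Gaussian noise;
* 12-bit quantization (round half away from zero, then clip).

The exponential-saturation form is a stand-in chosen as the simplest monotone
model with a near-linear early regime and a plateau; it is not a physical
claim.  Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .errors import InputError
from .imaging import FrameStack, LayoutEntry, SurfaceLayout, write_frame_stack

__all__ = [
    "DarkeningModel",
    "NoiseModel",
    "CampaignNoise",
    "CampaignDesign",
    "SessionRecord",
    "true_surface_pi",
    "render_session",
    "iter_campaign_sessions",
    "campaign_ground_truth",
    "generate_campaign",
    "quantize",
]

MAX_12BIT = 4095


def quantize(values: np.ndarray, max_value: int = MAX_12BIT) -> np.ndarray:
    """Round half away from zero, then clip to [0, max_value].

    Half-away rounding (rather than banker's rounding) keeps output identical
    across platforms and libraries.
    """
    rounded = np.sign(values) * np.floor(np.abs(values) + 0.5)
    return np.clip(rounded, 0, max_value).astype(np.uint16)


@dataclass(frozen=True)
class DarkeningModel:
    """Saturating-exponential darkening of one surface.

    ``concentration`` may be a constant (dose accrues linearly) or a callable
    C(t) integrated numerically.  Only the product ``k·v_d·C`` matters; with
    the defaults ``k = v_d = 1`` the concentration is the per-day dose rate.
    """

    pi_0: float = 3900.0
    pi_sat: float = 800.0
    k: float = 1.0
    v_d: float = 1.0
    concentration: float | Callable[[float], float] = 0.002

    def __post_init__(self) -> None:
        if not 0 <= self.pi_sat < self.pi_0 <= MAX_12BIT:
            raise InputError(
                f"require 0 <= pi_sat < pi_0 <= {MAX_12BIT}; "
                f"got pi_sat={self.pi_sat}, pi_0={self.pi_0}"
            )
        if self.k < 0 or self.v_d < 0:
            raise InputError("k and v_d must be >= 0")

    def dose(self, t: float) -> float:
        """Cumulative dose D(t) = ∫ v_d·C(τ) dτ from 0 to t."""
        if t < 0:
            raise InputError("t must be >= 0")
        if callable(self.concentration):
            grid = np.linspace(0.0, t, max(int(np.ceil(t)) * 4, 2))
            conc = np.array([self.concentration(x) for x in grid])
            return float(self.v_d * np.trapezoid(conc, grid))
        return float(self.v_d * self.concentration * t)

    @property
    def initial_rate(self) -> float:
        """dPI/dt at t = 0 for constant concentration: −k·(pi_0 − pi_sat)·v_d·C."""
        c0 = self.concentration(0.0) if callable(self.concentration) else self.concentration
        return -self.k * (self.pi_0 - self.pi_sat) * self.v_d * c0


def true_surface_pi(model: DarkeningModel, t: float) -> float:
    """Noise-free surface PI after exposure time t."""
    return model.pi_sat + (model.pi_0 - model.pi_sat) * np.exp(-model.k * model.dose(t))


@dataclass(frozen=True)
class NoiseModel:
    """Concrete noise realization parameters for one rendered session.

    ``offset`` (additive PI) and ``gain`` (multiplicative) are shared by every
    surface in the photograph; ``flicker_sd`` is the sd of a per-frame
    multiplicative factor (mean 1); ``pixel_sd`` is additive per-pixel
    Gaussian noise in PI.
    """

    offset: float = 0.0
    gain: float = 1.0
    flicker_sd: float = 0.0
    pixel_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InputError("gain must be > 0")
        if self.flicker_sd < 0 or self.pixel_sd < 0:
            raise InputError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CampaignNoise:
    """Distributions the campaign draws per-session NoiseModels from.

    Defaults describe a stable LED lightbox: ~20 PI (0.5% of full scale)
    session-to-session brightness offset, 0.2% gain drift, 0.2% frame
    flicker, 10 PI per-pixel sensor noise.
    """

    offset_sd: float = 20.0
    gain_sd: float = 0.002
    flicker_sd: float = 0.002
    pixel_sd: float = 10.0


def render_session(
    surface_pis: dict[str, float],
    layout: SurfaceLayout,
    noise: NoiseModel | None = None,
    n_frames: int = 20,
    frame_shape: tuple[int, int] = (256, 256),
    backdrop: float = 2048.0,
    session_id: str = "",
    bit_depth: int = 12,
) -> FrameStack:
    """Render one lightbox photograph as a quantized frame stack.

    Each pixel is ``clip(round(gain·f_j·pi + offset + ε), 0, full_scale)``
    with flicker factor ``f_j`` per frame j and per-pixel noise ε.  Pixels
    outside every ROI sit at the mid-gray ``backdrop`` (so a mis-specified
    ROI is visible in measurements).  Deterministic for a fixed seed.
    """
    noise = noise or NoiseModel()
    max_value = 2**bit_depth - 1
    for name, pi in surface_pis.items():
        if not 0 <= pi <= max_value:
            raise InputError(f"surface {name!r} PI {pi} outside [0, {max_value}]")
    base = np.full(frame_shape, float(backdrop))
    for e in layout.entries:
        rs, cs = e.slices()
        base[rs, cs] = surface_pis[e.name]
    rng = np.random.default_rng(noise.seed)
    flicker = (
        rng.normal(1.0, noise.flicker_sd, size=n_frames)
        if noise.flicker_sd > 0
        else np.ones(n_frames)
    )
    frames = noise.gain * flicker[:, None, None] * base[None, :, :] + noise.offset
    if noise.pixel_sd > 0:
        frames = frames + rng.normal(0.0, noise.pixel_sd, size=frames.shape)
    return FrameStack(
        frames=quantize(frames, max_value),
        bit_depth=bit_depth,
        session_id=session_id,
        capture_label="synthetic lightbox render",
    )


@dataclass(frozen=True)
class CampaignDesign:
    """A field campaign's stated world.

    Defaults mirror an 8-month deployment: 20 indoor locations, duplicate
    samplers per location, imaging at days 0/33/55/90/118/173/209/258, an
    unexposed reference surface in every photograph.  Per-location dose rates
    (``k·v_d·C`` per day) default to a geometric ladder from 3e-4 (slowest
    location first crosses the 1% threshold between days 33 and 55) to
    1.3e-2; a saturation probe optionally deploys a fresh replacement sampler
    mid-campaign at the fastest-darkening location.
    """

    n_locations: int = 20
    samplers_per_location: int = 2
    sampling_times: tuple[float, ...] = (0, 33, 55, 90, 118, 173, 209, 258)
    location_dose_rates: tuple[float, ...] | None = None
    baseline_pi: float = 3900.0
    baseline_pi_sd: float = 15.0
    reference_pi: float = 3950.0
    pi_sat: float = 800.0
    sampler_efficiency_sd: float = 0.05
    n_frames: int = 20
    frame_shape: tuple[int, int] = (256, 256)
    roi_side: int = 49
    time_unit: str = "day"
    replacement_start_time: float | None = None
    replacement_dose_rate: float = 0.04

    def dose_rates(self) -> np.ndarray:
        if self.location_dose_rates is not None:
            rates = np.asarray(self.location_dose_rates, dtype=float)
            if len(rates) != self.n_locations:
                raise InputError("location_dose_rates length must equal n_locations")
            return rates
        return np.geomspace(3e-4, 1.3e-2, self.n_locations)

    def layout(self) -> SurfaceLayout:
        rows, cols = self.frame_shape
        return SurfaceLayout(
            [
                LayoutEntry("sample", "sample", rows // 2, cols // 4, self.roi_side),
                LayoutEntry(
                    "reference", "reference", rows // 2, 3 * cols // 4, self.roi_side
                ),
            ]
        )


@dataclass(frozen=True)
class SessionRecord:
    """One rendered session plus its ground truth."""

    session_id: str
    sampler_id: str
    location_id: str
    role: str  # "original" | "replacement"
    time: float  # campaign clock
    exposure_time: float  # time since this sampler's deployment
    true_pi: float
    true_delta_pi: float
    dose_rate: float  # this sampler's k·v_d·C (efficiency jitter included)
    initial_rate: float  # configured initial darkening rate, PI per unit time
    stack: FrameStack


def _sampler_table(design: CampaignDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-sampler model parameters (baseline PI jitter, efficiency)."""
    rates = design.dose_rates()
    if design.replacement_start_time is not None:
        # the probe location (fastest darkening, as in the field protocol)
        # runs at the probe dose rate so its original pair saturates
        rates = rates.copy()
        rates[int(np.argmax(rates))] = design.replacement_dose_rate
    rows = []
    for i in range(design.n_locations):
        loc = f"L{i + 1:02d}"
        for j in range(design.samplers_per_location):
            rows.append(
                {
                    "sampler_id": f"{loc}{chr(ord('A') + j)}",
                    "location_id": loc,
                    "role": "original",
                    "start_time": 0.0,
                    "location_rate": rates[i],
                }
            )
    if design.replacement_start_time is not None:
        probe_loc = f"L{int(np.argmax(rates)) + 1:02d}"
        rows.append(
            {
                "sampler_id": f"{probe_loc}R",
                "location_id": probe_loc,
                "role": "replacement",
                "start_time": float(design.replacement_start_time),
                "location_rate": design.replacement_dose_rate,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    table["pi_0"] = np.clip(
        design.baseline_pi + rng.normal(0.0, design.baseline_pi_sd, size=n),
        design.pi_sat + 1.0,
        MAX_12BIT,
    )
    # per-sampler deposition efficiency spread between co-located replicates
    table["dose_rate"] = table["location_rate"] * np.exp(
        rng.normal(0.0, design.sampler_efficiency_sd, size=n)
    )
    # the replacement probe replicates the location's exposure regime exactly
    if design.replacement_start_time is not None:
        table.loc[table["role"] == "replacement", "dose_rate"] = (
            design.replacement_dose_rate
        )
    return table


def iter_campaign_sessions(
    design: CampaignDesign,
    noise: CampaignNoise | None = None,
    seed: int = 0,
) -> Iterator[SessionRecord]:
    """Yield every session of the campaign (one photograph per sampler per
    sampling time), rendered with freshly drawn session-level drift.

    Memory stays bounded: stacks are produced one at a time.
    """
    noise = noise if noise is not None else CampaignNoise()
    root = np.random.SeedSequence(seed)
    param_seed, session_seed = root.spawn(2)
    samplers = _sampler_table(design, np.random.default_rng(param_seed))
    layout = design.layout()
    session_rng = np.random.default_rng(session_seed)
    for row in samplers.itertuples():
        model = DarkeningModel(
            pi_0=row.pi_0,
            pi_sat=design.pi_sat,
            k=1.0,
            v_d=1.0,
            concentration=row.dose_rate,
        )
        pi_start = true_surface_pi(model, 0.0)
        for t in design.sampling_times:
            if t < row.start_time:
                continue
            exposure = t - row.start_time
            pi_true = true_surface_pi(model, exposure)
            session_noise = NoiseModel(
                offset=float(session_rng.normal(0.0, noise.offset_sd)),
                gain=float(session_rng.normal(1.0, noise.gain_sd)),
                flicker_sd=noise.flicker_sd,
                pixel_sd=noise.pixel_sd,
                seed=int(session_rng.integers(0, 2**31 - 1)),
            )
            session_id = f"{row.sampler_id}_t{int(t):04d}"
            stack = render_session(
                {"sample": pi_true, "reference": design.reference_pi},
                layout,
                noise=session_noise,
                n_frames=design.n_frames,
                frame_shape=design.frame_shape,
                session_id=session_id,
            )
            yield SessionRecord(
                session_id=session_id,
                sampler_id=row.sampler_id,
                location_id=row.location_id,
                role=row.role,
                time=float(t),
                exposure_time=float(exposure),
                true_pi=float(pi_true),
                true_delta_pi=float(pi_true - pi_start),
                dose_rate=float(row.dose_rate),
                initial_rate=float(model.initial_rate),
                stack=stack,
            )


def campaign_ground_truth(records: Iterator[SessionRecord] | list[SessionRecord]) -> pd.DataFrame:
    """Ground-truth table (one row per session) from session records."""
    return pd.DataFrame(
        [
            {
                "session_id": r.session_id,
                "sampler_id": r.sampler_id,
                "location_id": r.location_id,
                "role": r.role,
                "time": r.time,
                "exposure_time": r.exposure_time,
                "true_pi": r.true_pi,
                "true_delta_pi": r.true_delta_pi,
                "dose_rate": r.dose_rate,
                "initial_rate": r.initial_rate,
            }
            for r in records
        ]
    )


def generate_campaign(
    design: CampaignDesign,
    out_dir: str | Path,
    noise: CampaignNoise | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a whole campaign to ``out_dir``: one multi-frame TIFF per
    session, ``layout.yaml``, ``manifest.csv`` (sampler, location, role,
    time per session file) and ``ground_truth.csv``.  Returns the ground
    truth.  Byte-identical for identical design + noise + seed.
    """
    out = Path(out_dir)
    sessions_dir = out / "sessions"
    sessions_dir.mkdir(parents=True, exist_ok=True)
    design.layout().to_yaml(out / "layout.yaml")
    manifest_rows = []
    truth_rows = []
    for rec in iter_campaign_sessions(design, noise=noise, seed=seed):
        fname = f"{rec.session_id}.tiff"
        write_frame_stack(rec.stack, sessions_dir / fname)
        manifest_rows.append(
            {
                "session_file": f"sessions/{fname}",
                "session_id": rec.session_id,
                "sampler_id": rec.sampler_id,
                "location_id": rec.location_id,
                "role": rec.role,
                "time": rec.time,
            }
        )
        truth_rows.append(rec)
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    truth = campaign_ground_truth(truth_rows)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return truth
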