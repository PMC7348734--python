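"""Reading, validating and summarizing lightbox image stacks.

One imaging session is one lightbox photograph of a passively exposed filter
surface placed side-by-side with an unexposed reference surface, exported as a
multi-frame grayscale TIFF (typically 20 frames of 12-bit data stored in a
16-bit container).  This module reads those stacks, maps named surfaces to
rectangular regions of interest (ROIs) via an explicit layout file, pools mean
pixel intensity (PI) over all ROI pixels and frames, and produces a per-frame
QC report (over-saturation, flicker visibility, frame-count deviations).

Pixel intensity is unitless: 0 is perfect black, ``2**bit_depth - 1`` perfect
white.  12-bit data are commonly padded into 16-bit containers; values above
the declared full scale are treated as an error, never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import BitDepthError, FormatError, InputError, LayoutError

__all__ = [
    "FrameStack",
    "LayoutEntry",
    "SurfaceLayout",
    "FrameQCReport",
    "read_frame_stack",
    "write_frame_stack",
    "extract_roi_mean",
    "qc_frames",
]

DEFAULT_ROI_SIDE = 49


@dataclass
class FrameStack:
    """A session's raw pixel data: ``frames`` is (frame, row, column).

    ``max_value`` is the full-scale value implied by ``bit_depth``; every
    pixel must lie in ``[0, max_value]``.
    """

    frames: np.ndarray
    bit_depth: int
    session_id: str = ""
    capture_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be 3-D (frame, row, col); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1 or self.frames[0].size == 0:
            raise InputError("frame stack is empty")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise FormatError(f"pixel data must be integer, got {self.frames.dtype}")
        if self.frames.min() < 0:
            raise FormatError("negative pixel values in stack")
        if self.frames.max() > self.max_value:
            raise BitDepthError(
                f"pixel value {int(self.frames.max())} exceeds full scale "
                f"{self.max_value} for {self.bit_depth}-bit data"
            )

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass(frozen=True)
class LayoutEntry:
    """One named surface: a square ROI given by center pixel and odd side."""

    name: str
    role: str  # "sample" | "reference"
    center_row: int
    center_col: int
    side: int = DEFAULT_ROI_SIDE

    def __post_init__(self) -> None:
        if self.role not in ("sample", "reference"):
            raise LayoutError(f"role must be 'sample' or 'reference', got {self.role!r}")
        if self.side < 1 or self.side % 2 == 0:
            raise LayoutError(f"ROI side must be a positive odd integer, got {self.side}")

    def slices(self) -> tuple[slice, slice]:
        h = self.side // 2
        return (
            slice(self.center_row - h, self.center_row + h + 1),
            slice(self.center_col - h, self.center_col + h + 1),
        )

    def within(self, frame_shape: tuple[int, int]) -> bool:
        h = self.side // 2
        return (
            self.center_row - h >= 0
            and self.center_col - h >= 0
            and self.center_row + h < frame_shape[0]
            and self.center_col + h < frame_shape[1]
        )


@dataclass
class SurfaceLayout:
    """Named surfaces in the camera field of view; exactly one reference."""

    entries: list[LayoutEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        refs = [e for e in self.entries if e.role == "reference"]
        if len(refs) != 1:
            raise LayoutError(
                f"layout must contain exactly one reference surface, found {len(refs)}"
            )
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise LayoutError("surface names must be unique")

    @property
    def reference(self) -> LayoutEntry:
        return next(e for e in self.entries if e.role == "reference")

    @property
    def samples(self) -> list[LayoutEntry]:
        return [e for e in self.entries if e.role == "sample"]

    def entry(self, name: str) -> LayoutEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise LayoutError(f"no surface named {name!r} in layout")

    def validate_for(self, stack: FrameStack) -> None:
        for e in self.entries:
            if not e.within(stack.frame_shape):
                raise LayoutError(
                    f"ROI for surface {e.name!r} falls outside frame bounds "
                    f"{stack.frame_shape}"
                )

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurfaceLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "surfaces" not in doc:
            raise LayoutError(f"layout file {path} must contain a 'surfaces' list")
        default_side = int(doc.get("roi_side", DEFAULT_ROI_SIDE))
        entries = [
            LayoutEntry(
                name=str(s["name"]),
                role=str(s["role"]),
                center_row=int(s["center_row"]),
                center_col=int(s["center_col"]),
                side=int(s.get("side", default_side)),
            )
            for s in doc["surfaces"]
        ]
        return cls(entries)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "surfaces": [
                {
                    "name": e.name,
                    "role": e.role,
                    "center_row": e.center_row,
                    "center_col": e.center_col,
                    "side": e.side,
                }
                for e in self.entries
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_frame_stack(
    path: str | Path | Sequence[str | Path],
    expected_bit_depth: int = 12,
    session_id: str = "",
    capture_label: str = "",
) -> FrameStack:
    """Read a multi-frame grayscale TIFF (or an ordered set of single-frame
    TIFFs) as one session's :class:`FrameStack`.

    The stored container depth may exceed ``expected_bit_depth`` (12-bit data
    are routinely padded into 16-bit TIFFs); any pixel above
    ``2**expected_bit_depth - 1`` raises :class:`BitDepthError` rather than
    being rescaled.
    """
    if isinstance(path, (list, tuple)):
        if len(path) == 0:
            raise InputError("empty list of frame files")
        arrays = [_read_gray(p) for p in path]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise FormatError(f"frame files disagree in shape: {sorted(shapes)}")
        frames = np.stack(arrays)
        label = capture_label or str(path[0])
    else:
        frames = _read_gray(path)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        label = capture_label or str(path)
    return FrameStack(
        frames=frames,
        bit_depth=expected_bit_depth,
        session_id=session_id or Path(label).stem,
        capture_label=label,
    )


def _read_gray(path: str | Path) -> np.ndarray:
    with tifffile.TiffFile(path) as tf:
        photometric = tf.pages[0].photometric
        if photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK,
            tifffile.PHOTOMETRIC.MINISWHITE,
        ):
            raise FormatError(
                f"{path}: not a grayscale image (photometric={photometric.name})"
            )
        arr = tf.asarray()
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: pixel data must be integer, got {arr.dtype}")
    return arr


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF (lossless round trip)."""
    dtype = np.uint8 if stack.bit_depth <= 8 else np.uint16
    tifffile.imwrite(path, stack.frames.astype(dtype), photometric="minisblack")


def extract_roi_mean(stack: FrameStack, entry: LayoutEntry) -> float:
    """Mean pixel intensity of one surface: all ROI pixels pooled over all
    frames in a single arithmetic mean (identical to the mean of per-frame
    means for a fixed ROI). Unrounded."""
    if not entry.within(stack.frame_shape):
        raise LayoutError(
            f"ROI for surface {entry.name!r} (center ({entry.center_row},"
            f"{entry.center_col}), side {entry.side}) outside frame bounds "
            f"{stack.frame_shape}"
        )
    rs, cs = entry.slices()
    return float(stack.frames[:, rs, cs].mean())


@dataclass
class FrameQCReport:
    """Per-frame quality control for one session.

    ``frame_table`` has one row per frame: the fraction of ROI pixels sitting
    at full scale, the per-surface ROI means (so flicker outliers are visible),
    and an ``over_saturated`` flag.
    """

    session_id: str
    frame_table: pd.DataFrame
    frame_count_mismatch: bool
    expected_frames: int | None

    @property
    def over_saturated(self) -> np.ndarray:
        return self.frame_table["over_saturated"].to_numpy()

    @property
    def any_flag(self) -> bool:
        return bool(self.over_saturated.any() or self.frame_count_mismatch)


def qc_frames(
    stack: FrameStack,
    layout: SurfaceLayout,
    saturation_fraction_limit: float = 0.01,
    expected_frames: int | None = None,
) -> FrameQCReport:
    """Report-only QC: flag frames whose fraction of ROI pixels at full scale
    exceeds ``saturation_fraction_limit``, expose per-frame ROI means, and
    note deviations from the expected frame count."""
    layout.validate_for(stack)
    rows = []
    for j in range(stack.n_frames):
        frame = stack.frames[j]
        roi_pixels = []
        row: dict[str, object] = {"frame": j}
        for e in layout.entries:
            rs, cs = e.slices()
            region = frame[rs, cs]
            roi_pixels.append(region.ravel())
            row[f"mean_{e.name}"] = float(region.mean())
        pooled = np.concatenate(roi_pixels)
        frac = float((pooled == stack.max_value).mean())
        row["fraction_at_max"] = frac
        row["over_saturated"] = frac > saturation_fraction_limit
        rows.append(row)
    table = pd.DataFrame(rows)
    mismatch = expected_frames is not None and stack.n_frames != expected_frames
    return FrameQCReport(
        session_id=stack.session_id,
        frame_table=table,
        frame_count_mismatch=bool(mismatch),
        expected_frames=expected_frames,
    )
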