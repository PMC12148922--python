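"""Reading multiframe SWE clips into a uniform frame-stack model.

Clips are multiframe DICOM files: an ordered stack of 8-bit RGB frames with a
colour elastogram overlay blended onto the greyscale B-mode image. Pixel
spacing (mm/pixel) must be present — every downstream grid is defined in
physical units — and frame timing defaults to the scanner's 11 Hz B-mode rate
when the file carries no frame-time attribute.

Coordinate convention used throughout the package: row-major, origin at the
top-left, 0-based indices, half-open ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pydicom

logger = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "ClipMeta",
    "ClipParseError",
    "CalibrationError",
    "read_swe_clip",
    "attach_meta",
    "GROUPS",
    "MUSCLES",
    "TASKS",
    "ORIENTATIONS",
    "REPEATED_TASKS",
]

GROUPS = ("knee_OA", "old_control", "young_control")
MUSCLES = (
    "gastrocnemius_medialis",
    "vastus_lateralis",
    "vastus_medialis",
    "biceps_femoris",
)
TASKS = ("baseline", "lift_shank", "double_leg_stance", "single_leg_stance")
ORIENTATIONS = ("longitudinal", "transverse")
#: every condition except the resting baseline is recorded three times
REPEATED_TASKS = ("lift_shank", "double_leg_stance", "single_leg_stance")

DEFAULT_BMODE_RATE_HZ = 11.0


class ClipParseError(RuntimeError):
    """The file is not a readable multiframe image clip."""


class CalibrationError(RuntimeError):
    """Physical calibration (pixel spacing) is missing or invalid."""


@dataclass
class FrameStack:
    """Ordered RGB frames with physical pixel spacing and frame timing."""

    frames: np.ndarray  # (n_frames, rows, cols, 3) uint8
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    frame_rate_hz: float
    source_id: str = ""
    meta: "ClipMeta | None" = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 4 or frames.shape[3] != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be (n>=1, rows, cols, 3)")
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise CalibrationError("pixel spacing must be positive")
        self.frames = frames

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


@dataclass(frozen=True)
class ClipMeta:
    """Recording-condition labels attached to one clip."""

    participant_id: str
    group: str
    muscle: str
    task: str
    orientation: str
    repetition: int = 1
    painful_rank: int | None = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        for val, allowed, name in (
            (self.group, GROUPS, "group"),
            (self.muscle, MUSCLES, "muscle"),
            (self.task, TASKS, "task"),
            (self.orientation, ORIENTATIONS, "orientation"),
        ):
            if val not in allowed:
                raise ValueError(f"unknown {name} {val!r}; allowed: {allowed}")
        if self.task == "baseline":
            if self.repetition != 1:
                raise ValueError("baseline is recorded once; repetition must be 1")
        elif self.repetition not in (1, 2, 3):
            raise ValueError("repeated tasks have repetition in {1, 2, 3}")
        if self.painful_rank is not None and self.painful_rank not in (1, 2):
            raise ValueError("painful_rank must be 1, 2 or None")

    @property
    def key(self) -> tuple[str, str, str, str, int]:
        """Join key used by all downstream tables."""
        return (
            self.participant_id,
            self.muscle,
            self.task,
            self.orientation,
            self.repetition,
        )


def read_swe_clip(path) -> FrameStack:
    """Read a multiframe DICOM clip into a :class:`FrameStack`.

    Greyscale single-sample files are accepted with the channel replicated to
    RGB. Missing pixel data raises :class:`ClipParseError`; a missing or zero
    ``PixelSpacing`` raises :class:`CalibrationError` naming the attribute.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pragma: no cover - pydicom error wording varies
        raise ClipParseError(f"cannot parse DICOM file {path}: {exc}") from exc
    if "PixelData" not in ds:
        logger.warning("rejected %s: no PixelData", path)
        raise ClipParseError(f"{path}: file has no PixelData")
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None or len(spacing) != 2 or float(spacing[0]) <= 0 or float(spacing[1]) <= 0:
        logger.warning("rejected %s: missing/invalid PixelSpacing", path)
        raise CalibrationError(
            f"{path}: attribute PixelSpacing is missing or non-positive; "
            "physical calibration is required"
        )
    arr = ds.pixel_array
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if arr.ndim == 2:  # single greyscale frame
        arr = arr[None]
    if arr.ndim == 3:
        if arr.shape[-1] == 3 and n_frames == 1:
            arr = arr[None]  # single RGB frame
        else:  # multiframe greyscale: replicate channels
            arr = np.repeat(arr[..., None], 3, axis=-1)
    frame_time_ms = getattr(ds, "FrameTime", None)
    rate = 1000.0 / float(frame_time_ms) if frame_time_ms else DEFAULT_BMODE_RATE_HZ
    stack = FrameStack(
        frames=arr.astype(np.uint8),
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        frame_rate_hz=rate,
        source_id=str(getattr(ds, "SOPInstanceUID", path)),
    )
    logger.info("accepted %s: %d frames @ %.1f Hz", path, len(stack), rate)
    return stack


def attach_meta(stack: FrameStack, record: ClipMeta) -> FrameStack:
    """Attach recording-condition labels to a clip (validated on construction)."""
    stack.meta = record
    return stack
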