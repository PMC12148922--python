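"""Grid segmentation of the elastogram and per-square statistics with QC.

The decoded elastogram is tiled into 14 squares of 4 mm x 4 mm — two rows
(A: upper, B: lower) of seven columns — after discarding the elastogram's
top 1 mm, which lies against the superficial fascia and carries boundary
artefacts. Per square and per elastogram, six statistics are extracted over
the valid (coloured) pixels plus colour-coverage and saturation counts.

Quality control follows two rules: a square with less than 50% coloured
pixels is excluded (exactly 50% is retained), and an elastogram with more
than half of its 14 squares excluded (i.e. 8 or more) is discarded entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .elastogram import ElastogramFrame

__all__ = [
    "SquareGrid",
    "SquareFrameMetrics",
    "FrameQC",
    "GridSizingError",
    "SQUARE_SIDE_MM",
    "DISCARD_TOP_MM",
    "COLORED_PCT_CUTOFF",
    "build_grid",
    "square_metrics",
    "apply_qc",
]

SQUARE_SIDE_MM = 4.0
DISCARD_TOP_MM = 1.0
N_ROWS, N_COLS = 2, 7
COLORED_PCT_CUTOFF = 50.0

SQUARE_IDS = tuple(f"{row}{col}" for row in "AB" for col in range(1, N_COLS + 1))


class GridSizingError(ValueError):
    """The overlay region is too small for the full 2x7 grid."""


@dataclass(frozen=True)
class SquareGrid:
    """Pixel bounds of the 14 analysis squares, in overlay-local coordinates.

    ``squares`` maps labels A1..A7 (upper row), B1..B7 (lower row) to
    half-open ``(row0, row1, col0, col1)`` rectangles. All squares share one
    pixel size; anchoring is the top-left of the region retained after the
    1 mm discard (``anchor="center"`` centres the grid horizontally instead).
    """

    squares: dict[str, tuple[int, int, int, int]]
    discard_rows: int
    square_px: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.squares) != N_ROWS * N_COLS:
            raise ValueError("grid must hold exactly 14 squares")


def build_grid(
    shape: tuple[int, int] | ElastogramFrame,
    pixel_spacing_mm: tuple[float, float] | None = None,
    *,
    anchor: str = "top_left",
) -> SquareGrid:
    """Tile the overlay region into the 2x7 grid of 4 mm squares.

    The top ``ceil(1 mm / row_spacing)`` pixel rows are discarded (never keep
    any part of the artefact strip); square sides are ``round(4 mm / spacing)``
    pixels per axis. Leftover right/bottom margins stay unused.
    """
    if isinstance(shape, ElastogramFrame):
        pixel_spacing_mm = shape.pixel_spacing_mm
        shape = shape.shape
    if pixel_spacing_mm is None:
        raise ValueError("pixel_spacing_mm required when shape is a tuple")
    rows, cols = shape
    sr, sc = pixel_spacing_mm
    discard = math.ceil(DISCARD_TOP_MM / sr)
    side_r = round(SQUARE_SIDE_MM / sr)
    side_c = round(SQUARE_SIDE_MM / sc)
    need_r = discard + N_ROWS * side_r
    need_c = N_COLS * side_c
    if rows < need_r or cols < need_c:
        raise GridSizingError(
            f"overlay region of {rows * sr:.1f} x {cols * sc:.1f} mm cannot hold "
            f"the 2x7 grid of {SQUARE_SIDE_MM:g} mm squares below a "
            f"{DISCARD_TOP_MM:g} mm discard strip "
            f"(needs {need_r * sr:.1f} x {need_c * sc:.1f} mm)"
        )
    if anchor == "top_left":
        col_origin = 0
    elif anchor == "center":
        col_origin = (cols - need_c) // 2
    else:
        raise ValueError("anchor must be 'top_left' or 'center'")
    squares = {}
    for ri, row_label in enumerate("AB"):
        for ci in range(N_COLS):
            r0 = discard + ri * side_r
            c0 = col_origin + ci * side_c
            squares[f"{row_label}{ci + 1}"] = (r0, r0 + side_r, c0, c0 + side_c)
    return SquareGrid(squares=squares, discard_rows=discard, square_px=(side_r, side_c))


@dataclass
class SquareFrameMetrics:
    """Statistics of one square in one elastogram, over valid pixels only.

    ``included`` records the per-square QC outcome (coloured coverage of at
    least 50%). When no valid pixel exists the six statistics are NaN and
    ``defined`` is False. ``sd_swv`` uses the n-1 denominator and is 0.0 for
    a single pixel; ``iqr_swv`` uses linear-interpolation quantiles.
    """

    square_id: str
    elasto_index: int
    max_swv: float
    mean_swv: float
    median_swv: float
    sd_swv: float
    iqr_swv: float
    colored_pct: float
    saturated_n: int
    saturated_pct: float
    included: bool
    defined: bool


@dataclass(frozen=True)
class FrameQC:
    """Per-elastogram QC outcome: discarded iff more than half the squares fail."""

    elasto_index: int
    n_squares_excluded: int

    @property
    def frame_discarded(self) -> bool:
        return self.n_squares_excluded > (N_ROWS * N_COLS) // 2


def square_metrics(
    frame: ElastogramFrame,
    grid: SquareGrid,
    *,
    colored_cutoff_pct: float = COLORED_PCT_CUTOFF,
) -> list[SquareFrameMetrics]:
    """Extract the six per-square statistics plus coverage and saturation.

    Saturated pixels stay in the statistics: saturation is reported as its
    own count/percentage, not applied as a filter.
    """
    out = []
    for sid in SQUARE_IDS:
        r0, r1, c0, c1 = grid.squares[sid]
        vals = frame.swv[r0:r1, c0:c1]
        valid = frame.valid_mask[r0:r1, c0:c1]
        sat = frame.saturated_mask[r0:r1, c0:c1]
        n_pix = vals.size
        n_valid = int(valid.sum())
        colored_pct = 100.0 * n_valid / n_pix
        v = vals[valid]
        if n_valid:
            stats = dict(
                max_swv=float(v.max()),
                mean_swv=float(v.mean()),
                median_swv=float(np.median(v)),
                sd_swv=float(v.std(ddof=1)) if n_valid > 1 else 0.0,
                iqr_swv=float(
                    np.percentile(v, 75, method="linear")
                    - np.percentile(v, 25, method="linear")
                ),
                defined=True,
            )
        else:
            stats = dict(
                max_swv=np.nan, mean_swv=np.nan, median_swv=np.nan,
                sd_swv=np.nan, iqr_swv=np.nan, defined=False,
            )
        out.append(
            SquareFrameMetrics(
                square_id=sid,
                elasto_index=frame.elasto_index,
                colored_pct=colored_pct,
                saturated_n=int(sat.sum()),
                saturated_pct=100.0 * int(sat.sum()) / n_pix,
                included=colored_pct >= colored_cutoff_pct,
                **stats,
            )
        )
    return out


def apply_qc(metrics: list[SquareFrameMetrics]) -> FrameQC:
    """Per-elastogram QC from its 14 square records.

    Exclusion is strict below 50% coverage (50.0% retained, 49.9% excluded);
    the elastogram is discarded iff strictly more than half of the 14 squares
    are excluded, i.e. 8 or more (7 of 14 retains the frame).
    """
    if len(metrics) != N_ROWS * N_COLS:
        raise ValueError(f"expected {N_ROWS * N_COLS} square records, got {len(metrics)}")
    excluded = sum(not m.included for m in metrics)
    return FrameQC(elasto_index=metrics[0].elasto_index, n_squares_excluded=excluded)
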