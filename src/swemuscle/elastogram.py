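"""Elastogram overlay handling: locate the colour overlay inside B-mode frames,
deduplicate elastogram updates, and decode overlay colours to shear wave velocity.

Clinical SWE systems superimpose a colour-coded stiffness map (the elastogram)
on the greyscale B-mode image. The colour scale maps shear wave velocity (SWV,
m/s) to a perceptual blue-to-red ramp over the device's measurement range
(here [0, 10) m/s). Pixels where the tracker produced no stiffness estimate are
left greyscale ("void"); pixels above the reliable range (> 9.9 m/s) are
rendered at the top of the scale and flagged as saturated.

The vendor's exact lookup table is proprietary; this module ships a default
ramp with 256 control points so encoding and decoding are exact inverses by
construction, and accepts any user-supplied table of control points (e.g. one
calibrated from a screenshot of the on-screen colour bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ColorScale",
    "ElastogramFrame",
    "OverlayDetectionError",
    "detect_overlay_region",
    "dedupe_elastograms",
    "decode_elastogram",
    "chroma",
]


class OverlayDetectionError(RuntimeError):
    """No colour overlay could be located in any frame of the clip."""


def chroma(rgb: np.ndarray) -> np.ndarray:
    """Colourfulness of 8-bit RGB pixels as max(R,G,B) - min(R,G,B).

    Zero for pure greys; cheap and monotone, which is all that is needed to
    separate overlay pixels from the greyscale B-mode background.
    """
    rgb = np.asarray(rgb)
    return rgb.max(axis=-1).astype(np.int16) - rgb.min(axis=-1).astype(np.int16)


def _default_lut_colors(n: int) -> np.ndarray:
    """Blue->cyan->green->yellow->red ramp with ``n`` distinct 8-bit colours."""
    anchors = np.array(
        [
            (0.0, 0.0, 140.0),  # deep blue, slow
            (0.0, 70.0, 255.0),
            (0.0, 255.0, 255.0),  # cyan
            (60.0, 255.0, 60.0),  # green
            (255.0, 255.0, 0.0),  # yellow
            (255.0, 60.0, 0.0),
            (180.0, 0.0, 0.0),  # dark red, fast
        ]
    )
    # arc-length parameterisation keeps consecutive LUT entries well separated
    seg = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
    t_anchor = np.concatenate([[0.0], np.cumsum(seg)]) / seg.sum()
    t = np.linspace(0.0, 1.0, n)
    cols = np.stack(
        [np.interp(t, t_anchor, anchors[:, c]) for c in range(3)], axis=1
    )
    out = np.rint(cols).astype(np.uint8)
    if len(np.unique(out.astype(np.int32) @ np.array([1, 256, 65536]))) != n:
        raise ValueError("LUT colours are not pairwise distinct")
    return out


@dataclass(frozen=True)
class ColorScale:
    """Ordered colour <-> velocity control points over ``[vmin, vmax)``.

    Parameters
    ----------
    colors
        ``(n, 3)`` uint8 control-point colours, ordered by velocity.
    velocities
        ``(n,)`` strictly increasing velocities (m/s) in ``[vmin, vmax)``.
    saturation_threshold
        Velocities decoded above this value are flagged saturated
        (device-reliable range ends at 9.9 m/s for a 10 m/s scale).
    chroma_threshold
        Pixels with chroma at or below this value count as grey (void).
    """

    colors: np.ndarray
    velocities: np.ndarray
    vmin: float = 0.0
    vmax: float = 10.0
    saturation_threshold: float = 9.9
    chroma_threshold: int = 8

    def __post_init__(self) -> None:
        colors = np.asarray(self.colors, dtype=np.uint8)
        velocities = np.asarray(self.velocities, dtype=float)
        if colors.ndim != 2 or colors.shape[1] != 3 or colors.shape[0] < 2:
            raise ValueError("need >= 2 RGB control points")
        if colors.shape[0] != velocities.shape[0]:
            raise ValueError("colors and velocities must align")
        if not np.all(np.diff(velocities) > 0):
            raise ValueError("control-point velocities must be strictly increasing")
        if not (self.vmin <= velocities[0] and velocities[-1] < self.vmax):
            raise ValueError("control points must span [vmin, vmax)")
        if not self.saturation_threshold < self.vmax:
            raise ValueError("saturation_threshold must be below vmax")
        object.__setattr__(self, "colors", colors)
        object.__setattr__(self, "velocities", velocities)

    @classmethod
    def default(cls, n: int = 256) -> "ColorScale":
        """The package's default scale: ``n`` control points over [0, 10) m/s."""
        vel = 0.0 + np.arange(n) * (10.0 / n)
        return cls(colors=_default_lut_colors(n), velocities=vel)

    @property
    def quantization_step(self) -> float:
        return float(np.max(np.diff(self.velocities)))

    def quantize(self, swv: np.ndarray | float) -> np.ndarray | float:
        """Nearest representable velocity (what encode+decode returns)."""
        idx = self._nearest_index(np.asarray(swv, dtype=float))
        out = self.velocities[idx]
        return float(out) if np.isscalar(swv) else out

    def _nearest_index(self, swv: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.velocities, swv)
        pos = np.clip(pos, 1, len(self.velocities) - 1)
        left = self.velocities[pos - 1]
        right = self.velocities[pos]
        idx = np.where(swv - left <= right - swv, pos - 1, pos)
        return np.clip(idx, 0, len(self.velocities) - 1)

    def encode(self, swv: np.ndarray) -> np.ndarray:
        """Velocities (m/s) -> control-point colours, nearest-point quantised."""
        swv = np.asarray(swv, dtype=float)
        return self.colors[self._nearest_index(swv)]

    @property
    def top_color(self) -> np.ndarray:
        """Colour used for saturated (out-of-range) measurements."""
        return self.colors[-1]


@dataclass
class ElastogramFrame:
    """One decoded elastogram: per-pixel SWV with validity/saturation masks.

    ``swv`` is NaN wherever ``valid_mask`` is False; ``saturated_mask`` is a
    subset of ``valid_mask``.
    """

    swv: np.ndarray
    valid_mask: np.ndarray
    saturated_mask: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    elasto_index: int

    def __post_init__(self) -> None:
        if not (self.swv.shape == self.valid_mask.shape == self.saturated_mask.shape):
            raise ValueError("swv and masks must share one shape")
        if np.any(self.saturated_mask & ~self.valid_mask):
            raise ValueError("saturated_mask must be a subset of valid_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.swv.shape


def detect_overlay_region(
    frames: Sequence[np.ndarray] | np.ndarray, scale: ColorScale
) -> tuple[int, int, int, int]:
    """Bounding box (row0, row1, col0, col1), half-open, of the colour overlay.

    A pixel belongs to the overlay if its chroma exceeds the scale's threshold
    in at least one frame. If several connected candidate regions exist, the
    largest by area wins (small colour annotations elsewhere on screen lose).
    The region is taken as constant for the whole clip: the probe is strapped
    in place and the overlay box does not move.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise OverlayDetectionError("no frames")
    colored = np.zeros(frames.shape[1:3], dtype=bool)
    for fr in frames:
        colored |= chroma(fr) > scale.chroma_threshold
    if not colored.any():
        raise OverlayDetectionError("no elastogram found (no coloured pixel in any frame)")
    labels, n = ndimage.label(colored)
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    sl = ndimage.find_objects((labels == best).astype(np.int8))[0]
    return (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop)


def dedupe_elastograms(
    frames: Sequence[np.ndarray] | np.ndarray,
    region: tuple[int, int, int, int],
) -> list[tuple[int, np.ndarray]]:
    """Collapse consecutive frames whose overlay pixels are identical.

    The B-mode stack refreshes at ~11 Hz while the elastogram updates at
    1.2-2.0 Hz, so each elastogram is repeated across several consecutive
    frames. Returns ``(first_frame_index, overlay_image)`` per distinct
    elastogram, in acquisition order.
    """
    r0, r1, c0, c1 = region
    if r1 <= r0 or c1 <= c0:
        raise ValueError("empty overlay region")
    out: list[tuple[int, np.ndarray]] = []
    prev: np.ndarray | None = None
    for i, fr in enumerate(frames):
        crop = np.asarray(fr)[r0:r1, c0:c1]
        if prev is None or not np.array_equal(crop, prev):
            out.append((i, crop.copy()))
            prev = crop
    return out


def decode_elastogram(
    image: np.ndarray,
    scale: ColorScale,
    pixel_spacing_mm: tuple[float, float],
    elasto_index: int = 0,
    *,
    unblend_alpha: float | None = None,
    unblend_background: np.ndarray | None = None,
) -> ElastogramFrame:
    """Decode an RGB overlay crop to a shear-wave-velocity field.

    Each coloured pixel (chroma above the scale threshold) is matched to its
    nearest control point in RGB space, then refined by projecting onto the
    segment towards the nearer neighbouring control point and interpolating
    the velocity linearly along it. Grey pixels are void (``valid_mask``
    False); velocities above the saturation threshold set ``saturated_mask``.

    ``unblend_alpha`` optionally inverts an alpha blend of the overlay over a
    stated background before lookup (for devices that store the composited
    screen rather than raw overlay colours): ``raw = (pixel - (1-a)*bg) / a``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a non-empty HxWx3 RGB image")
    valid = chroma(image) > scale.chroma_threshold
    swv = np.full(image.shape[:2], np.nan)
    saturated = np.zeros(image.shape[:2], dtype=bool)
    if valid.any():
        pix = image[valid].astype(float)
        if unblend_alpha is not None:
            bg = 0.0 if unblend_background is None else np.asarray(
                unblend_background, dtype=float
            )
            pix = np.clip((pix - (1.0 - unblend_alpha) * bg) / unblend_alpha, 0, 255)
        lut = scale.colors.astype(float)
        vel = scale.velocities
        idx = cKDTree(lut).query(pix, k=1)[1]
        v = vel[idx].copy()
        # refine between the nearest control point and its closer neighbour
        for step in (-1, 1):
            nb = idx + step
            ok = (nb >= 0) & (nb < len(vel))
            if not ok.any():
                continue
            a = lut[idx[ok]]
            b = lut[nb[ok]]
            ab = b - a
            denom = np.einsum("ij,ij->i", ab, ab)
            t = np.einsum("ij,ij->i", pix[ok] - a, ab) / np.where(denom == 0, 1, denom)
            t = np.clip(t, 0.0, 0.5)  # beyond the midpoint the neighbour is nearest
            cand = vel[idx[ok]] + t * (vel[nb[ok]] - vel[idx[ok]])
            resid = np.linalg.norm(pix[ok] - (a + t[:, None] * ab), axis=1)
            base = np.linalg.norm(pix[ok] - lut[idx[ok]], axis=1)
            take = resid < base
            sub = v[ok]
            sub[take] = cand[take]
            v[ok] = sub
        swv[valid] = v
        saturated[valid] = v > scale.saturation_threshold
    return ElastogramFrame(
        swv=swv,
        valid_mask=valid,
        saturated_mask=saturated,
        pixel_spacing_mm=tuple(pixel_spacing_mm),
        elasto_index=elasto_index,
    )
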