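"""End-to-end clip processing: detection -> dedupe -> decode -> grid -> QC -> trial.

Thin orchestration over the per-stage modules, plus optional per-elastogram
diagnostic dumps (decoded velocity raster and mask overlay as PNG).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .aggregate import TrialSummary, metrics_table, trial_summary
from .clip_io import ClipMeta, FrameStack, read_swe_clip
from .elastogram import ColorScale, decode_elastogram, dedupe_elastograms, detect_overlay_region
from .grid_metrics import apply_qc, build_grid, square_metrics

logger = logging.getLogger(__name__)

__all__ = ["process_stack", "process_clip"]


def process_stack(
    stack: FrameStack,
    scale: ColorScale | None = None,
    *,
    meta: ClipMeta | None = None,
    diagnostics_dir: str | Path | None = None,
):
    """Run the full extraction on an in-memory frame stack.

    Returns ``(TrialSummary, per-clip long-format metrics DataFrame)``.
    """
    scale = scale or ColorScale.default()
    meta = meta or stack.meta
    region = detect_overlay_region(stack.frames, scale)
    logger.info("%s: overlay region rows %d:%d cols %d:%d", stack.source_id, *region)
    raws = dedupe_elastograms(stack.frames, region)
    logger.info("%s: %d distinct elastograms in %d frames", stack.source_id, len(raws), len(stack))
    frames = [
        decode_elastogram(img, scale, stack.pixel_spacing_mm, elasto_index=i)
        for i, (_, img) in enumerate(raws)
    ]
    grid = build_grid(frames[0])
    per_frame = [square_metrics(f, grid) for f in frames]
    qc = [apply_qc(m) for m in per_frame]
    if diagnostics_dir is not None:
        _dump_diagnostics(frames, Path(diagnostics_dir), stack.source_id)
    summary = trial_summary(per_frame, qc, meta=meta)
    return summary, metrics_table(per_frame, qc, meta=meta)


def process_clip(path, scale: ColorScale | None = None, *, meta: ClipMeta | None = None, **kw):
    """Read a DICOM clip from ``path`` and run :func:`process_stack`."""
    return process_stack(read_swe_clip(path), scale, meta=meta, **kw)


def _dump_diagnostics(frames, out_dir: Path, source_id: str) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    tag = source_id.replace("/", "_")[-40:] or "clip"
    for f in frames:
        swv8 = np.zeros(f.shape, dtype=np.uint8)
        ok = f.valid_mask
        if ok.any():
            swv8[ok] = np.clip(f.swv[ok] / 10.0 * 255, 0, 255).astype(np.uint8)
        masks = np.zeros(f.shape, dtype=np.uint8)
        masks[f.valid_mask] = 100
        masks[f.saturated_mask] = 200
        iio.imwrite(out_dir / f"{tag}_e{f.elasto_index:03d}_swv.png", swv8)
        iio.imwrite(out_dir / f"{tag}_e{f.elasto_index:03d}_masks.png", masks)
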