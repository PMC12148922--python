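"""Ground-truth phantom SWE clips and simulated three-group cohorts.

The phantom generator emulates, at the image level, what the scanner exports:
a multiframe RGB DICOM whose greyscale B-mode refreshes at 11 Hz while the
colour elastogram overlay updates at 1.2-2.0 Hz, so each elastogram is
repeated over consecutive B-mode frames. Void (no-estimate) pixels show the
grey background through the overlay; saturated pixels (> 9.9 m/s) are painted
with the top colour of the scale. The exact per-pixel velocity field, masks
and frame-to-elastogram index are returned as ground truth alongside the file
(never re-derived from it), making every downstream stage testable without
any external data.

The cohort simulator draws trial-level shear wave velocities for the three
study groups (knee OA, age/sex-matched old controls, young controls) over the
four recording tasks and both transducer orientations, with the default group
medians taken from the study's reported condition medians and additive
between-/within-subject Gaussian variation.

No acoustics are simulated; phantoms are image-level objects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .clip_io import DEFAULT_BMODE_RATE_HZ, GROUPS, REPEATED_TASKS, TASKS
from .elastogram import ColorScale

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "make_phantom_clip",
    "simulate_cohort",
    "simulate_questionnaire",
    "default_cohort_spec",
    "DEFAULT_GROUP_MEDIANS",
    "DEFAULT_QUESTIONNAIRE_PROFILES",
]

#: default condition medians (m/s) per (group, muscle, task, orientation),
#: for the gastrocnemius medialis (GM) and vastus lateralis (VL) muscles
DEFAULT_GROUP_MEDIANS: dict[tuple[str, str, str, str], float] = {}


def _fill_default_medians() -> None:
    gm, vl = "gastrocnemius_medialis", "vastus_lateralis"
    lon = {  # (task, muscle) -> (knee_OA, old_control, young_control)
        ("baseline", gm): (4.098, 4.254, 4.050),
        ("lift_shank", gm): (4.114, 4.240, 4.103),
        ("double_leg_stance", gm): (4.580, 5.373, 5.264),
        ("single_leg_stance", gm): (6.292, 6.803, 7.754),
        ("baseline", vl): (4.122, 4.229, 4.040),
        ("lift_shank", vl): (4.086, 4.162, 4.027),
        ("double_leg_stance", vl): (4.192, 4.294, 4.142),
        ("single_leg_stance", vl): (4.257, 4.248, 4.112),
    }
    tra = {
        ("baseline", gm): (4.225, 4.048, 4.013),
        ("lift_shank", gm): (4.164, 4.099, 4.058),
        ("double_leg_stance", gm): (4.270, 4.227, 4.142),
        ("single_leg_stance", gm): (4.405, 4.390, 4.309),
        ("baseline", vl): (4.235, 4.185, 4.004),
        ("lift_shank", vl): (4.094, 4.097, 4.030),
        ("double_leg_stance", vl): (4.099, 4.230, 4.165),
        ("single_leg_stance", vl): (4.093, 4.309, 4.084),
    }
    for orient, table in (("longitudinal", lon), ("transverse", tra)):
        for (task, muscle), vals in table.items():
            for group, v in zip(GROUPS, vals):
                DEFAULT_GROUP_MEDIANS[(group, muscle, task, orient)] = v


_fill_default_medians()


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic SWE clip.

    ``field_kind`` selects the ground-truth velocity field over the overlay
    region: spatially constant, a linear top-to-bottom gradient from
    ``base_swv`` to ``lesion_swv``, or a constant field with a stiffer/softer
    rectangular patch (``lesion_bounds_mm`` in overlay-local mm).
    """

    field_kind: str = "constant"
    base_swv: float = 4.2
    lesion_swv: float | None = None
    lesion_bounds_mm: tuple[float, float, float, float] | None = None
    void_fraction: float = 0.10
    saturation_fraction: float = 0.0
    duration_s: float = 30.0
    bmode_rate_hz: float = DEFAULT_BMODE_RATE_HZ
    elasto_rate_hz: float = 1.6
    pixel_spacing_mm: tuple[float, float] = (0.2, 0.2)
    noise_sd: float = 0.05
    seed: int = 0
    frame_shape: tuple[int, int] = (96, 176)
    overlay_region: tuple[int, int, int, int] = (20, 76, 14, 160)

    def __post_init__(self) -> None:
        if self.field_kind not in ("constant", "linear_gradient", "patch_lesion"):
            raise ValueError(f"unknown field_kind {self.field_kind!r}")
        if self.field_kind != "constant" and self.lesion_swv is None:
            raise ValueError(f"{self.field_kind} requires lesion_swv")
        if self.field_kind == "patch_lesion" and self.lesion_bounds_mm is None:
            raise ValueError("patch_lesion requires lesion_bounds_mm")
        for v in (self.base_swv, self.lesion_swv):
            if v is not None and not (0.0 < v < 10.0):
                raise ValueError("velocities must lie in (0, 10) m/s")
        if not (0 <= self.void_fraction and 0 <= self.saturation_fraction):
            raise ValueError("fractions must be non-negative")
        if self.void_fraction + self.saturation_fraction > 1:
            raise ValueError("void_fraction + saturation_fraction must be <= 1")
        if self.duration_s not in (20.0, 30.0, 20, 30):
            raise ValueError("duration_s must be 20 or 30 s")
        if not (1.2 <= self.elasto_rate_hz <= 2.0):
            raise ValueError("elasto_rate_hz must lie in [1.2, 2.0]")
        if self.duration_s * self.elasto_rate_hz < 1:
            raise ValueError("clip must contain at least one elastogram")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        r0, r1, c0, c1 = self.overlay_region
        if not (0 <= r0 < r1 <= self.frame_shape[0] and 0 <= c0 < c1 <= self.frame_shape[1]):
            raise ValueError("overlay_region must fit inside frame_shape")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.bmode_rate_hz))

    def frame_elasto_index(self) -> np.ndarray:
        """Elastogram index per B-mode frame (half-open tick convention).

        Elastogram ``i`` covers frames with timestamps in
        ``[i/elasto_rate, (i+1)/elasto_rate)``; a 1e-9 guard absorbs binary
        floating-point jitter exactly at tick boundaries.
        """
        j = np.arange(self.n_frames)
        return np.floor(
            j * self.elasto_rate_hz / self.bmode_rate_hz + 1e-9
        ).astype(int)


@dataclass
class GroundTruth:
    """Exact phantom state: what a perfect analysis pipeline must recover.

    ``valid_mask`` is the union over elastograms (the void pattern is drawn
    afresh per elastogram, as tracking dropouts vary over time in real
    clips); per-elastogram masks and velocity fields are kept alongside.
    """

    field: np.ndarray  # (rows, cols) m/s over the overlay region
    valid_mask: np.ndarray
    saturated_mask: np.ndarray
    frame_elasto_index: np.ndarray
    overlay_region: tuple[int, int, int, int]
    spec: PhantomSpec
    elasto_fields: list[np.ndarray] = dc_field(default_factory=list)
    elasto_valid_masks: list[np.ndarray] = dc_field(default_factory=list)
    elasto_saturated_masks: list[np.ndarray] = dc_field(default_factory=list)

    @property
    def n_elastograms(self) -> int:
        return int(self.frame_elasto_index[-1]) + 1


def _smooth_fraction_mask(
    shape: tuple[int, int], fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Blobby boolean mask covering exactly ``round(fraction*size)`` pixels."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    k = int(round(fraction * noise.size))
    if k == 0:
        return np.zeros(shape, dtype=bool)
    thresh = np.partition(noise.ravel(), k - 1)[k - 1]
    mask = noise <= thresh
    # ties at the threshold could overshoot; trim deterministically
    extra = mask.sum() - k
    if extra > 0:
        idx = np.flatnonzero(mask.ravel() & (noise.ravel() == thresh))[:extra]
        flat = mask.ravel()
        flat[idx] = False
        mask = flat.reshape(shape)
    return mask


def _build_field(spec: PhantomSpec, shape: tuple[int, int]) -> np.ndarray:
    if spec.field_kind == "constant":
        return np.full(shape, spec.base_swv)
    if spec.field_kind == "linear_gradient":
        col = np.linspace(spec.base_swv, spec.lesion_swv, shape[0])
        return np.repeat(col[:, None], shape[1], axis=1)
    # patch_lesion
    field = np.full(shape, spec.base_swv)
    r0mm, r1mm, c0mm, c1mm = spec.lesion_bounds_mm
    sr, sc = spec.pixel_spacing_mm
    r0, r1 = int(round(r0mm / sr)), int(round(r1mm / sr))
    c0, c1 = int(round(c0mm / sc)), int(round(c1mm / sc))
    field[max(r0, 0) : r1, max(c0, 0) : c1] = spec.lesion_swv
    return field


def make_phantom_clip(
    spec: PhantomSpec,
    out_path,
    scale: ColorScale | None = None,
    *,
    write_sidecars: bool = True,
) -> tuple[Path, GroundTruth]:
    """Write a multiframe RGB DICOM phantom clip and return its ground truth.

    The clip holds ``round(duration_s * 11)`` B-mode frames; the overlay
    region repeats each elastogram until the next elastogram tick. Void
    pixels are rendered zero-chroma (grey), saturated pixels at the top
    colour of the scale. Sidecars (``.truth.csv`` frame→elastogram map and a
    ``.masks.png`` label raster: 0 void / 1 valid / 2 saturated) document the
    ground truth next to the file.
    """
    scale = scale or ColorScale.default()
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.frame_shape
    r0, r1, c0, c1 = spec.overlay_region
    oshape = (r1 - r0, c1 - c0)

    field = _build_field(spec, oshape).copy()
    # saturation marks genuinely over-range tissue: static across the clip
    saturated_static = _smooth_fraction_mask(oshape, spec.saturation_fraction, rng)
    field[saturated_static] = scale.vmax + 0.5  # truly out of range

    # static speckle-like B-mode background (greyscale, zero chroma)
    bmode = rng.integers(25, 95, size=(rows, cols), dtype=np.uint8)
    bmode = np.repeat(bmode[..., None], 3, axis=-1)

    idx_per_frame = spec.frame_elasto_index()
    n_elasto = int(idx_per_frame[-1]) + 1

    # render each distinct elastogram once; the void (no-estimate) pattern is
    # redrawn per elastogram, like real shear-wave tracking dropouts
    lo = scale.velocities[0] + scale.quantization_step
    hi = scale.saturation_threshold - scale.quantization_step
    overlays = []
    elasto_fields = []
    elasto_valid = []
    elasto_sat = []
    for _ in range(n_elasto):
        void = _smooth_fraction_mask(oshape, spec.void_fraction, rng)
        valid = ~void
        saturated = saturated_static & valid
        f = field.copy()
        if spec.noise_sd > 0:
            f = f + rng.normal(0.0, spec.noise_sd, size=oshape)
            f[valid & ~saturated] = np.clip(f[valid & ~saturated], lo, hi)
            f[saturated_static] = scale.vmax + 0.5
        img = bmode[r0:r1, c0:c1].copy()
        enc = scale.encode(np.clip(f, scale.velocities[0], scale.velocities[-1]))
        img[valid] = enc[valid]
        img[saturated] = scale.top_color
        overlays.append(img)
        elasto_fields.append(f)
        elasto_valid.append(valid)
        elasto_sat.append(saturated)

    frames = np.empty((spec.n_frames, rows, cols, 3), dtype=np.uint8)
    frames[:] = bmode
    for j, e in enumerate(idx_per_frame):
        frames[j, r0:r1, c0:c1] = overlays[e]

    _write_multiframe_dicom(frames, spec, out_path)

    truth = GroundTruth(
        field=field,
        valid_mask=np.logical_or.reduce(elasto_valid),
        saturated_mask=saturated_static,
        frame_elasto_index=idx_per_frame,
        overlay_region=spec.overlay_region,
        spec=spec,
        elasto_fields=elasto_fields,
        elasto_valid_masks=elasto_valid,
        elasto_saturated_masks=elasto_sat,
    )
    if write_sidecars:
        _write_sidecars(out_path, truth)
    return out_path, truth


def _write_multiframe_dicom(frames: np.ndarray, spec: PhantomSpec, out_path: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UltrasoundMultiFrameImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Rows, ds.Columns = frames.shape[1:3]
    ds.NumberOfFrames = frames.shape[0]
    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "RGB"
    ds.PlanarConfiguration = 0
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{spec.pixel_spacing_mm[0]:g}", f"{spec.pixel_spacing_mm[1]:g}"]
    ds.FrameTime = f"{1000.0 / spec.bmode_rate_hz:.6g}"  # ms per frame
    ds.PixelData = frames.tobytes()
    ds.save_as(str(out_path), enforce_file_format=True)


def _write_sidecars(out_path: Path, truth: GroundTruth) -> None:
    with open(f"{out_path}.truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "elasto_index"])
        for j, e in enumerate(truth.frame_elasto_index):
            w.writerow([j, int(e)])
    labels = np.zeros(truth.field.shape, dtype=np.uint8)
    labels[truth.valid_mask] = 1
    labels[truth.saturated_mask] = 2
    iio.imwrite(f"{out_path}.masks.png", labels * 100)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated three-group cohort of trial-level SWV values."""

    n_per_group: Mapping[str, int]
    group_medians: Mapping[tuple[str, str, str, str], float]
    between_subject_sd: float = 0.25
    within_subject_sd: float = 0.15
    n_repetitions: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("empty group list")
        if not set(self.n_per_group) <= set(GROUPS):
            raise ValueError(f"groups must be a subset of {GROUPS}")
        if any(v <= 0 for v in self.group_medians.values()):
            raise ValueError("all medians must be > 0")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("SDs must be >= 0")

    def reps_for(self, task: str) -> int:
        if self.n_repetitions is not None and task in self.n_repetitions:
            return self.n_repetitions[task]
        return 3 if task in REPEATED_TASKS else 1


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Study-sized cohort: 21 knee OA + 21 old controls + 20 young controls."""
    kw = dict(
        n_per_group={"knee_OA": 21, "old_control": 21, "young_control": 20},
        group_medians=DEFAULT_GROUP_MEDIANS,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


#: per-group (mean, SD) profiles of the patient-reported outcomes and
#: demographics used when simulating questionnaire tables: KOOS subscores
#: (0-100, higher = better), perceived stiffness (KOOS items S6+S7, 0-8,
#: higher = stiffer), Tampa Scale of Kinesiophobia (17-68), age and BMI
DEFAULT_QUESTIONNAIRE_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "knee_OA": dict(
        perceived=(3.3, 1.8), KOOS_pain=(55.4, 13.8), KOOS_symptoms=(55.9, 18.0),
        KOOS_ADL=(70.7, 16.6), KOOS_sport=(28.5, 22.6), KOOS_QoL=(34.2, 18.3),
        TSK=(21.2, 5.5), age=(57.4, 6.3), BMI=(25.3, 3.9),
    ),
    "old_control": dict(
        perceived=(0.1, 0.4), KOOS_pain=(97.8, 4.5), KOOS_symptoms=(96.8, 3.6),
        KOOS_ADL=(99.3, 1.7), KOOS_sport=(96.4, 8.2), KOOS_QoL=(97.3, 7.5),
        TSK=(17.9, 5.4), age=(58.0, 5.6), BMI=(24.2, 3.7),
    ),
    "young_control": dict(
        perceived=(0.2, 0.9), KOOS_pain=(97.6, 6.1), KOOS_symptoms=(95.5, 6.4),
        KOOS_ADL=(99.5, 1.3), KOOS_sport=(98.9, 3.5), KOOS_QoL=(96.9, 9.6),
        TSK=(15.7, 3.6), age=(22.1, 2.8), BMI=(22.2, 2.3),
    ),
}


def simulate_questionnaire(participants, seed: int = 0):
    """Per-participant questionnaire/demographic table for a simulated cohort.

    ``participants``: a DataFrame holding ``participant_id`` and ``group``
    (e.g. the output of :func:`simulate_cohort`). Scores are Gaussian draws
    around the group profiles, clipped to their instruments' ranges; the
    perceived-stiffness sum is split into the two items S6 and S7.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    base = participants[["participant_id", "group"]].drop_duplicates()
    rows = []
    for _, p in base.iterrows():
        prof = DEFAULT_QUESTIONNAIRE_PROFILES[p.group]
        rec = {"participant_id": p.participant_id}
        for name, (mu, sd) in prof.items():
            val = rng.normal(mu, sd)
            if name.startswith("KOOS"):
                val = float(np.clip(val, 0, 100))
            elif name == "perceived":
                val = float(np.clip(round(val), 0, 8))
            elif name == "TSK":
                val = float(np.clip(val, 17, 68))
            rec[name] = val
        s6 = int(min(rec["perceived"], 4))
        rec["S6"], rec["S7"] = s6, int(rec["perceived"] - s6)
        del rec["perceived"]
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec):
    """Draw a long-format table of trial-level shear wave velocities.

    One row per participant x muscle x task x orientation x repetition. Each
    participant is assigned one (most painful / matched) muscle among those
    present in ``group_medians``; values are the condition median plus a
    participant-level offset (``between_subject_sd``) plus trial noise
    (``within_subject_sd``), truncated at 0.05 m/s. Deterministic for a fixed
    seed.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    muscles = sorted({k[1] for k in spec.group_medians})
    tasks = [t for t in TASKS if any(k[2] == t for k in spec.group_medians)]
    orientations = sorted({k[3] for k in spec.group_medians})

    # matched design: participant index i gets the same muscle in every group
    n_max = max(spec.n_per_group.values())
    matched_muscle = [muscles[int(rng.integers(len(muscles)))] for _ in range(n_max)]

    rows = []
    for group in GROUPS:
        if group not in spec.n_per_group:
            continue
        for i in range(spec.n_per_group[group]):
            pid = f"{group}_{i + 1:02d}"
            muscle = matched_muscle[i]
            offset = rng.normal(0.0, spec.between_subject_sd) if spec.between_subject_sd else 0.0
            for task in tasks:
                for orient in orientations:
                    key = (group, muscle, task, orient)
                    if key not in spec.group_medians:
                        continue
                    med = spec.group_medians[key]
                    for rep in range(1, spec.reps_for(task) + 1):
                        noise = (
                            rng.normal(0.0, spec.within_subject_sd)
                            if spec.within_subject_sd
                            else 0.0
                        )
                        rows.append(
                            {
                                "participant_id": pid,
                                "group": group,
                                "muscle": muscle,
                                "task": task,
                                "orientation": orient,
                                "repetition": rep,
                                "swv": max(med + offset + noise, 0.05),
                            }
                        )
    return pd.DataFrame(rows)
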