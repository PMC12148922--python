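"""Collapse per-square per-frame metrics to trial, repetition and participant
level, and compute the two ratio measures.

A trial (one clip) is summarised in two median stages: per square, the
temporal median over that square's QC-included elastograms; then the median
over the 14 per-square medians. Repetitions of a condition collapse by median
(mean by configuration). Two unitless ratios describe muscle anisotropy and
activation response:

* longitudinal/transverse SWV ratio — anisotropy indicator per task;
* single-leg-stance/baseline SWV ratio — stiffness change with activation,
  per orientation (``direction="baseline_over_task"`` gives the reciprocal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clip_io import ClipMeta
from .grid_metrics import FrameQC, SquareFrameMetrics, SQUARE_IDS

__all__ = [
    "TrialSummary",
    "trial_summary",
    "metrics_table",
    "collapse_repetitions",
    "lt_ratio",
    "activation_ratio",
    "build_cohort_table",
    "summaries_to_trials",
]

TRIAL_KEY = ["participant_id", "muscle", "task", "orientation"]


@dataclass
class TrialSummary:
    """One clip collapsed to a single stiffness value plus QC bookkeeping."""

    meta: ClipMeta | None
    per_square_median: dict[str, float]
    trial_swv: float  # NaN when no square has an included frame
    frames_total: int
    frames_retained: int
    valid: bool
    reason: str = ""

    @property
    def inclusion_pct(self) -> float:
        return 100.0 * self.frames_retained / self.frames_total if self.frames_total else 0.0


def trial_summary(
    per_frame_metrics: list[list[SquareFrameMetrics]],
    qc: list[FrameQC],
    meta: ClipMeta | None = None,
) -> TrialSummary:
    """Collapse one clip's per-frame square metrics into a trial value.

    Discarded elastograms contribute nothing. Per square, the temporal median
    runs over the retained elastograms in which that square was included; the
    trial value is the median over squares having at least one included frame.
    """
    if not per_frame_metrics:
        raise ValueError("no frames in clip")
    if len(per_frame_metrics) != len(qc):
        raise ValueError("metrics and QC records must align")
    retained = [m for m, q in zip(per_frame_metrics, qc) if not q.frame_discarded]
    per_square: dict[str, float] = {}
    for sid in SQUARE_IDS:
        vals = [
            m.median_swv
            for frame in retained
            for m in frame
            if m.square_id == sid and m.included and m.defined
        ]
        per_square[sid] = float(np.median(vals)) if vals else math.nan
    defined = [v for v in per_square.values() if not math.isnan(v)]
    valid = bool(defined)
    return TrialSummary(
        meta=meta,
        per_square_median=per_square,
        trial_swv=float(np.median(defined)) if valid else math.nan,
        frames_total=len(per_frame_metrics),
        frames_retained=len(retained),
        valid=valid,
        reason="" if valid else "all elastograms discarded by QC",
    )


def metrics_table(
    per_frame_metrics: list[list[SquareFrameMetrics]],
    qc: list[FrameQC],
    meta: ClipMeta | None = None,
) -> pd.DataFrame:
    """Long-format per-clip table: one row per (elasto_index, square_id)."""
    rows = []
    qc_by_idx = {q.elasto_index: q for q in qc}
    for frame in per_frame_metrics:
        for m in frame:
            rows.append(
                {
                    "elasto_index": m.elasto_index,
                    "square_id": m.square_id,
                    "max_swv": m.max_swv,
                    "mean_swv": m.mean_swv,
                    "median_swv": m.median_swv,
                    "sd_swv": m.sd_swv,
                    "iqr_swv": m.iqr_swv,
                    "colored_pct": m.colored_pct,
                    "saturated_n": m.saturated_n,
                    "saturated_pct": m.saturated_pct,
                    "included": m.included,
                    "frame_discarded": qc_by_idx[m.elasto_index].frame_discarded,
                }
            )
    df = pd.DataFrame(rows)
    if meta is not None:
        for k, v in (
            ("participant_id", meta.participant_id),
            ("group", meta.group),
            ("muscle", meta.muscle),
            ("task", meta.task),
            ("orientation", meta.orientation),
            ("repetition", meta.repetition),
        ):
            df[k] = v
    return df


def collapse_repetitions(values, method: str = "median") -> float:
    """Collapse 1-3 repetition values of one condition; NaNs (invalid trials)
    are dropped, and no valid trial at all propagates NaN."""
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if not vals:
        return math.nan
    if method == "median":
        return float(np.median(vals))
    if method == "mean":
        return float(np.mean(vals))
    raise ValueError("method must be 'median' or 'mean'")


def lt_ratio(longitudinal: float, transverse: float) -> float:
    """Longitudinal-to-transverse SWV ratio (anisotropy indicator)."""
    if _missing(longitudinal) or _missing(transverse):
        return math.nan
    if longitudinal <= 0 or transverse <= 0:
        raise ValueError("velocities must be > 0")
    return longitudinal / transverse


def activation_ratio(
    single_leg: float, baseline: float, *, direction: str = "task_over_baseline"
) -> float:
    """Single-leg-stance-to-baseline SWV ratio (activation response).

    Values above 1 indicate stiffness rising with activation; the
    ``baseline_over_task`` direction returns the reciprocal.
    """
    if _missing(single_leg) or _missing(baseline):
        return math.nan
    if single_leg <= 0 or baseline <= 0:
        raise ValueError("velocities must be > 0")
    if direction == "task_over_baseline":
        return single_leg / baseline
    if direction == "baseline_over_task":
        return baseline / single_leg
    raise ValueError("direction must be 'task_over_baseline' or 'baseline_over_task'")


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def summaries_to_trials(summaries: list[TrialSummary]) -> pd.DataFrame:
    """Trial-level long table from clip summaries (requires attached meta)."""
    rows = []
    for s in summaries:
        if s.meta is None:
            raise ValueError("summaries must carry ClipMeta to form a cohort table")
        rows.append(
            {
                "participant_id": s.meta.participant_id,
                "group": s.meta.group,
                "muscle": s.meta.muscle,
                "task": s.meta.task,
                "orientation": s.meta.orientation,
                "repetition": s.meta.repetition,
                "swv": s.trial_swv,
                "inclusion_pct": s.inclusion_pct,
            }
        )
    return pd.DataFrame(rows)


def build_cohort_table(
    trials: pd.DataFrame,
    questionnaire: pd.DataFrame | None = None,
    *,
    collapse: str = "median",
    activation_direction: str = "task_over_baseline",
) -> pd.DataFrame:
    """One analysis row per participant x muscle x task x orientation.

    Repetitions collapse by ``collapse``; the anisotropy ratio joins on
    (participant, muscle, task), the activation ratio on rows of the
    single-leg-stance task per orientation. Questionnaire columns
    (KOOS subscores, S6/S7, TSK, age, BMI) join on participant_id, with
    perceived stiffness = S6 + S7. Measurements of first- and second-ranked
    painful muscles are pooled per muscle by keying on the muscle itself.
    """
    required = set(TRIAL_KEY + ["group", "repetition", "swv"])
    if not required <= set(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(required)}")
    dup = trials.duplicated(subset=TRIAL_KEY + ["repetition"], keep=False)
    if dup.any():
        offenders = (
            trials.loc[dup, TRIAL_KEY + ["repetition"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"duplicate trial keys: {offenders}")

    agg = (
        trials.groupby(TRIAL_KEY + ["group"], as_index=False)["swv"]
        .agg(lambda v: collapse_repetitions(v, method=collapse))
    )

    wide = agg.pivot_table(
        index=["participant_id", "group", "muscle", "task"],
        columns="orientation",
        values="swv",
    ).reset_index()
    if {"longitudinal", "transverse"} <= set(wide.columns):
        wide["lt_ratio"] = [
            lt_ratio(l, t) if not (_missing(l) or _missing(t)) else math.nan
            for l, t in zip(wide["longitudinal"], wide["transverse"])
        ]
    else:
        wide["lt_ratio"] = math.nan
    agg = agg.merge(
        wide[["participant_id", "muscle", "task", "lt_ratio"]],
        on=["participant_id", "muscle", "task"],
        how="left",
    )

    base = agg[agg["task"] == "baseline"][
        ["participant_id", "muscle", "orientation", "swv"]
    ].rename(columns={"swv": "_baseline_swv"})
    agg = agg.merge(base, on=["participant_id", "muscle", "orientation"], how="left")
    agg["activation_ratio"] = [
        activation_ratio(s, b, direction=activation_direction)
        if task == "single_leg_stance" and not (_missing(s) or _missing(b))
        else math.nan
        for task, s, b in zip(agg["task"], agg["swv"], agg["_baseline_swv"])
    ]
    agg = agg.drop(columns="_baseline_swv")

    if questionnaire is not None:
        q = questionnaire.copy()
        if {"S6", "S7"} <= set(q.columns) and "perceived_stiffness" not in q.columns:
            q["perceived_stiffness"] = q["S6"] + q["S7"]
        agg = agg.merge(q, on="participant_id", how="left", validate="many_to_one")
    return agg
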