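#!/usr/bin/env python
"""Generate the synthetic inputs for the downstream analyses.

Writes three ground-truth phantom clips (constant field, depth gradient,
stiff lesion with saturation) to scratch/clips/, a summary of their ground
truth to results/phantom_truth.csv, and a full study-sized simulated cohort
(21 knee OA / 21 old control / 20 young control; trial-level shear wave
velocities plus a questionnaire table) to results/.
"""

import sys
from pathlib import Path

import pandas as pd

from swemuscle.synthetic_data import (
    PhantomSpec,
    default_cohort_spec,
    make_phantom_clip,
    simulate_cohort,
    simulate_questionnaire,
)

ROOT = Path(__file__).resolve().parents[1]
CLIP_DIR = ROOT / "scratch" / "clips"
RESULTS = ROOT / "results"


def main(seed: int = 0) -> None:
    CLIP_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    phantoms = {
        "constant": PhantomSpec(
            field_kind="constant", base_swv=4.2, duration_s=30,
            elasto_rate_hz=1.6, void_fraction=0.10, noise_sd=0.05, seed=seed,
        ),
        "gradient": PhantomSpec(
            field_kind="linear_gradient", base_swv=3.5, lesion_swv=6.5,
            duration_s=30, elasto_rate_hz=1.6, void_fraction=0.10,
            noise_sd=0.05, seed=seed + 1,
        ),
        "lesion": PhantomSpec(
            field_kind="patch_lesion", base_swv=4.0, lesion_swv=8.0,
            lesion_bounds_mm=(3.0, 8.0, 6.0, 16.0), duration_s=20,
            elasto_rate_hz=1.2, void_fraction=0.15,
            saturation_fraction=0.05, noise_sd=0.05, seed=seed + 2,
        ),
    }
    rows = []
    for name, spec in phantoms.items():
        path = CLIP_DIR / f"{name}.dcm"
        _, truth = make_phantom_clip(spec, path)
        rows.append(
            {
                "clip": path.name,
                "field_kind": spec.field_kind,
                "base_swv": spec.base_swv,
                "lesion_swv": spec.lesion_swv,
                "n_frames": spec.n_frames,
                "n_elastograms": truth.n_elastograms,
                "void_fraction": spec.void_fraction,
                "saturation_fraction": spec.saturation_fraction,
            }
        )
        print(
            f"{path.name}: {spec.n_frames} frames, {truth.n_elastograms} "
            f"elastograms at {spec.elasto_rate_hz} Hz over {spec.duration_s:g} s"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "phantom_truth.csv", index=False)

    cohort = simulate_cohort(default_cohort_spec(seed=seed))
    cohort.to_csv(RESULTS / "cohort_trials.csv", index=False)
    quest = simulate_questionnaire(cohort, seed=seed + 10)
    quest.to_csv(RESULTS / "questionnaire.csv", index=False)
    print(
        f"cohort: {cohort.participant_id.nunique()} participants, "
        f"{len(cohort)} trials -> results/cohort_trials.csv"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
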