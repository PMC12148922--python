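#!/usr/bin/env python
"""Reliability of the repeated recordings and the a-priori power analysis.

ICC (two-way, absolute agreement, average of the 3 repetitions) with its 95%
CI and the standard error of measurement, per muscle x orientation x repeated
task of the simulated cohort; plus the a-priori sample sizes for the planned
group comparisons (one-way ANOVA as the parametric stand-in for the
Kruskal-Wallis test, and the ARE-corrected Wilcoxon-Mann-Whitney pairs).
"""

from pathlib import Path

import pandas as pd

from swemuscle.clip_io import REPEATED_TASKS
from swemuscle.stats import PowerSpec, anova_power_n, icc_3_3, wmw_power_n

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    trials = pd.read_csv(RESULTS / "cohort_trials.csv")
    rows = []
    for (muscle, task, orient), sub in trials.groupby(["muscle", "task", "orientation"]):
        if task not in REPEATED_TASKS:
            continue
        wide = sub.pivot_table(
            index="participant_id", columns="repetition", values="swv"
        )
        res = icc_3_3(wide.to_numpy())
        rows.append(
            {
                "muscle": muscle, "task": task, "orientation": orient,
                "icc": res.icc, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "sem_m_per_s": res.sem, "n_participants": res.n,
                "model": res.model,
            }
        )
    rel = pd.DataFrame(rows)
    rel.to_csv(RESULTS / "reliability.csv", index=False)
    print(
        f"reliability: ICC range {rel.icc.min():.3f}-{rel.icc.max():.3f}, "
        f"SEM range {rel.sem_m_per_s.min():.3f}-{rel.sem_m_per_s.max():.3f} m/s "
        f"over {len(rel)} condition cells"
    )

    spec = PowerSpec(effect_f=0.48, alpha=0.05, power=0.80, k_groups=3)
    power = pd.DataFrame(
        [
            {
                "test": "one-way ANOVA (3 groups)", "effect": "f = 0.48",
                "alpha": 0.05, "power": 0.80, "total_N": anova_power_n(spec),
            },
            {
                "test": "Wilcoxon-Mann-Whitney (ARE method)", "effect": "d = 0.96",
                "alpha": 0.05, "power": 0.80, "total_N": wmw_power_n(spec),
            },
        ]
    )
    power.to_csv(RESULTS / "power.csv", index=False)
    print(power.to_string(index=False))


if __name__ == "__main__":
    main()
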