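#!/usr/bin/env python
"""Group-level analysis of the simulated cohort.

Builds the analysis table (repetition collapse, anisotropy and activation
ratios, questionnaire join), then per muscle x task x orientation compares
the three groups with the Kruskal-Wallis test, following up significant
omnibus results with pairwise asymptotic Wilcoxon rank-sum tests, and
correlates stiffness with the patient-reported outcomes inside the knee-OA
group (Spearman). Writes tidy tables under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from swemuscle.aggregate import build_cohort_table
from swemuscle.stats import group_comparison, spearman

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

GROUP_ORDER = ["knee_OA", "old_control", "young_control"]
PRO_COLS = [
    "perceived_stiffness", "KOOS_pain", "KOOS_symptoms",
    "KOOS_ADL", "KOOS_sport", "KOOS_QoL", "TSK",
]


def iqr(v) -> float:
    return float(np.percentile(v, 75) - np.percentile(v, 25))


def compare_groups(tab: pd.DataFrame, value: str, out_rows: list) -> None:
    for (muscle, task, orient), sub in tab.groupby(["muscle", "task", "orientation"]):
        samples, present = [], []
        for g in GROUP_ORDER:
            v = sub.loc[sub.group == g, value].dropna().to_numpy()
            if len(v):
                samples.append(v)
                present.append(g)
        if len(samples) < 2:
            continue
        res = group_comparison(samples, labels=present)
        row = {
            "measure": value, "muscle": muscle, "task": task,
            "orientation": orient,
            "kruskal_H": res.statistic, "kruskal_p": res.p_value,
        }
        for g, v in zip(present, samples):
            row[f"{g}_median"] = float(np.median(v))
            row[f"{g}_iqr"] = iqr(v)
        if res.pairs:
            for pr in res.pairs:
                row[f"p_{pr.groups[0]}_vs_{pr.groups[1]}"] = pr.p_value
        out_rows.append(row)


def main() -> None:
    trials = pd.read_csv(RESULTS / "cohort_trials.csv")
    quest = pd.read_csv(RESULTS / "questionnaire.csv")
    tab = build_cohort_table(trials, quest)
    tab.to_csv(RESULTS / "cohort_table.csv", index=False)

    rows: list = []
    compare_groups(tab, "swv", rows)
    lt = tab.drop_duplicates(subset=["participant_id", "muscle", "task"]).assign(
        orientation="both"
    )
    compare_groups(lt, "lt_ratio", rows)
    compare_groups(tab[tab.task == "single_leg_stance"], "activation_ratio", rows)
    comp = pd.DataFrame(rows)
    comp.to_csv(RESULTS / "group_comparisons.csv", index=False)
    n_sig = int((comp["kruskal_p"] < 0.05).sum())
    print(f"group comparisons: {len(comp)} condition cells, {n_sig} significant omnibus tests")

    # Spearman correlations inside the knee-OA group
    oa = tab[tab.group == "knee_OA"]
    cor_rows = []
    for (muscle, task, orient), sub in oa.groupby(["muscle", "task", "orientation"]):
        for pro in PRO_COLS:
            sub2 = sub[["swv", pro]].dropna()
            if len(sub2) < 3 or sub2[pro].nunique() < 2 or sub2["swv"].nunique() < 2:
                continue
            res = spearman(sub2["swv"], sub2[pro])
            cor_rows.append(
                {
                    "muscle": muscle, "task": task, "orientation": orient,
                    "outcome": pro, "rho": res.rho, "p": res.p_value,
                    "n": res.n, "band": res.band,
                }
            )
    cors = pd.DataFrame(cor_rows)
    cors.to_csv(RESULTS / "correlations.csv", index=False)
    print(
        f"correlations (knee-OA group): {len(cors)} coefficients, "
        f"{int((cors['p'] < 0.05).sum())} significant"
    )


if __name__ == "__main__":
    main()
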