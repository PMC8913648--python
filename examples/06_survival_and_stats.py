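"""Intervention comparisons: survival curves and body-weight trajectories.

Simulates two treatment groups (high vs low hazard) with body-weight drift,
compares survival with the log-rank test, and compares per-animal
body-weight areas under the curve with the two-sided Wilcoxon rank-sum test.
"""

import numpy as np

import glycoferm as gf
from glycoferm.stats import SurvivalRecord, auc_trapezoid, logrank, wilcoxon_rank_sum

surv, weights = gf.simulate.generate_survival_weights(
    {"untreated": 0.12, "treated": 0.02}, n_per_group=12, seed=6,
    weight_drift={"untreated": -1.2, "treated": -0.3})

for g in ("untreated", "treated"):
    sub = surv[surv["group"] == g]
    print(f"{g}: {int(sub['event'].sum())}/{len(sub)} deaths by day 14")

recs = [SurvivalRecord(r.animal_id, r.group, r.time, bool(r.event))
        for r in surv.itertuples()]
res = logrank(recs)
print(f"log-rank: chi2 = {res.statistic:.2f}, p = {res.p_value:.4g}")

aucs = {g: [auc_trapezoid(a["day"].to_numpy(), a["weight_pct"].to_numpy())
            for _, a in weights[weights["group"] == g].groupby("animal_id")
            if len(a) > 1]
        for g in ("untreated", "treated")}
w = wilcoxon_rank_sum(aucs["untreated"], aucs["treated"])
print(f"body-weight AUC (per animal): untreated median "
      f"{np.median(aucs['untreated']):.0f}, treated median "
      f"{np.median(aucs['treated']):.0f}; Wilcoxon p = {w.p_value:.4g}")
print("\nA small log-rank p indicates different survival experiences; the"
      "\nAUC comparison integrates each animal's weight trajectory so early"
      "\ndeaths and sustained weight loss both lower the group's AUCs.")
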