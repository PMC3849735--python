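"""Cox regression and the three-poor-factor risk stratification.

Simulates a disease-free-survival cohort with known hazard ratios
(1.71 per SD of mitotic index, 2.20 for nodal involvement, 1.46 per
SD of the heterogeneity score), refits them by Cox partial likelihood,
and stratifies patients by the number of poor prognostic factors:
mitotic index > 10 per 1.7 mm², positive nodes, upper tercile of CP2.
"""

import numpy as np

import histohet as hh

cohort = hh.generate_cohort(hh.CohortSpec(n=2000), seed=3)
print(f"cohort: n={len(cohort)}, events={int(cohort.event.sum())}")

fit = hh.cox_fit(cohort, ["mitotic_index_std", "node_pos", "cp2"])
print("\nmultivariate Cox fit (true RRs 1.71, 2.20, 1.46):")
print(fit.summary().round(4).to_string())
print(f"score-equation residual: {hh.cox_score_residual(cohort, fit):.2e}")

flags = hh.upper_tercile_flag(cohort["cp2"])
groups = hh.assign_risk_groups(cohort, flags, mitotic_cut=10.0)
print("\nrisk groups:", groups.counts())

stat, p = hh.logrank_test(cohort["dfs_time"], cohort["event"], groups.group)
print(f"log-rank across the 3 groups: chi2={stat:.1f}, p={p:.3g}")

times = np.array([12.0, 60.0, 120.0])
for lab in ("0 factor", "1 or 2 factors", "3 factors"):
    sel = groups.group == lab
    km = hh.km_estimate(cohort.loc[sel, "dfs_time"], cohort.loc[sel, "event"])
    surv = ", ".join(f"S({int(t)}m)={km(t):.2f}" for t in times)
    print(f"  {lab:15s} {surv}")
print(
    "\nsurvival drops monotonically with the number of poor factors — the "
    "stratification carries the prognostic information of the joint model."
)
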