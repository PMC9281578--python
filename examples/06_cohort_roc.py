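"""Cohort-level classification: published distributions -> ROC report.

Draws a synthetic patient/control cohort from the published per-index
mean/SD table and asks, per index and condition, how well each index
separates the groups (AUC, Youden cut-off, sensitivity, specificity).
"""

from hrvdcan import CohortConfig, run_cohort_indexes

cohort, summary, report = run_cohort_indexes(CohortConfig(n_per_group=500,
                                                          seed=2))
sup = report[report.condition == "SUP"].set_index("index")

print("supine-rest ROC for the headline indexes (500 subjects/group):")
for index in ("sdnn_i", "rmssd", "tot_p", "sampen"):
    row = sup.loc[index]
    cut = f"< {row.cutoff:.0f}" if row.p < 0.05 else "   --"
    print(f"  {index:8s}  AUC {row.auc:.3f} (SE {row.se:.3f})  p {row.p:.2g}  "
          f"cut-off {cut}")
print()
print("Global-variability and vagal indexes separate the groups (AUC ~0.7); "
      "entropy does not (AUC ~0.5) - the discriminative signal lives in the "
      "amount, not the irregularity, of supine variability.")
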