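"""Full pipeline on a synthetic three-group cohort.

Three dynamical regimes stand in for healthy controls (near bifurcation),
minimally conscious patients (intermediate) and unresponsive patients
(saturated attractor).  Each subject's series is inverted, the landscape
measures are swept across time, and the across-time features feed a rank
test and a leave-one-out rule-learner classification.
"""

import pandas as pd

import lvscape as lv

spec = lv.CohortSpec(
    groups=(
        ("hc", "near_bifurcation", 10),
        ("mcs", "intermediate", 10),
        ("uws", "saturated", 10),
    ),
    T=80,
    seed=1,
)
subjects, sc = lv.generate_cohort(spec)

rows = []
for s in subjects:
    recovered = lv.lvt_transform(s.series, sc, g=spec.g)
    summary = lv.subject_summary(recovered)
    rows.append({"label": s.group, **summary.as_series().to_dict()})
frame = pd.DataFrame(rows)

show = ["frondosity_mean", "synchronicity", "coop_a_mean", "criticality_median"]
print("group means of selected features:")
print(frame.groupby("label").mean(numeric_only=True)[show].round(3).to_string())
print()
print("Saturated attractors give frondosity and synchronicity 1 with no")
print("cooperation; near-bifurcation dynamics show the opposite profile.")

features = [c for c in frame.columns if c != "label" and not c.startswith("diff_")]
pvals = lv.group_compare(frame, frame["label"], ("hc", "uws"), features=features)
thr = lv.bonferroni_threshold(0.05, len(features))
print(f"\nrank-test p-values below the corrected threshold {thr:.4f}: "
      f"{int((pvals < thr).sum())}/{len(features)} features")

extreme = frame[frame["label"].isin(["hc", "uws"])].reset_index(drop=True)
report = lv.loo_classify(extreme, features=features, learner="rule", seed=0)
print(f"leave-one-out accuracy (hc vs uws, rule learner): "
      f"{report.metrics['accuracy']:.2f}")
print("most frequently selected features (%f):")
print(report.feature_frequency.sort_values(ascending=False).head(3).to_string())
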