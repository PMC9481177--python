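"""One-off calibration check for the synthetic-cohort archetypes.

Runs small cohorts across several seeds and verifies that the qualitative
group ordering of the landscape measures holds robustly:

* frondosity and synchronicity: saturated > intermediate > near_bifurcation
* cooperation means and standard deviations: reversed
* median criticality: near_bifurcation lowest

The archetype parameters live in ``src/lvscape/config/archetypes.yaml``;
edit them there and re-run this script.  Usage::

    python scripts/calibrate_archetypes.py [--seeds 10] [--per-group 10] [--T 80]
"""

import argparse

import pandas as pd

import lvscape as lv
from lvscape.pipeline import subject_summary
from lvscape.transform import lvt_transform

ORDERINGS = [
    # (feature, ordered group names, direction)
    ("frondosity_mean", ("uws", "mcs", "hc"), "desc"),
    ("synchronicity", ("uws", "mcs", "hc"), "desc"),
    ("criticality_median", ("hc", "mcs", "uws"), "asc"),
] + [
    (f, ("hc", "mcs", "uws"), "desc")
    for f in (
        "coop_level_mean",
        "coop_level_sd",
        "coop_a_mean",
        "coop_a_sd",
        "coop_b_mean",
        "coop_b_sd",
        "coop_c_mean",
        "coop_c_sd",
    )
]


def group_means(seed: int, per_group: int, T: int) -> pd.DataFrame:
    spec = lv.CohortSpec(
        groups=(
            ("hc", "near_bifurcation", per_group),
            ("mcs", "intermediate", per_group),
            ("uws", "saturated", per_group),
        ),
        T=T,
        seed=seed,
    )
    subjects, sc = lv.generate_cohort(spec)
    rows = []
    for s in subjects:
        summ = subject_summary(lvt_transform(s.series, sc, g=spec.g))
        rows.append({"label": s.group, **summ.as_series().to_dict()})
    return pd.DataFrame(rows).groupby("label").mean(numeric_only=True)


def check(seed: int, per_group: int, T: int) -> list:
    gm = group_means(seed, per_group, T)
    failures = []
    for feat, order, direction in ORDERINGS:
        vals = [gm.loc[g, feat] for g in order]
        if direction == "asc":
            vals = vals[::-1]
        ok = all(a > b for a, b in zip(vals, vals[1:]))
        if not ok:
            failures.append((feat, dict(zip(order, vals))))
    return failures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--per-group", type=int, default=10)
    ap.add_argument("--T", type=int, default=80)
    args = ap.parse_args()
    n_bad = 0
    for seed in range(args.seeds):
        failures = check(seed, args.per_group, args.T)
        status = "ok" if not failures else f"FAIL {failures}"
        if failures:
            n_bad += 1
        print(f"seed {seed}: {status}")
    print(f"{args.seeds - n_bad}/{args.seeds} seeds satisfy all orderings")


if __name__ == "__main__":
    main()
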