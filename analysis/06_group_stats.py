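#!/usr/bin/env python
"""Genotype comparisons across every measure the earlier steps produced.

For each measure (SIN metric z-scores, day/night activity, sleep, circadian
period, climbing score, GSH/GSSG) the variance-homogeneity gate picks
one-way ANOVA + Tukey or Kruskal-Wallis + Dunn (Holm), and the full decision
trail is written to results/group_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from flysin.stats_report import StatsPolicy, _comparison_rows, choose_and_test

ROOT = Path(__file__).resolve().parents[1] / "results"


def _by_genotype(df, value_col):
    return {g: sub[value_col].to_numpy() for g, sub in df.groupby("genotype")}


def main() -> None:
    measures = {}
    sin = pd.read_csv(ROOT / "sin_zscores.csv")
    for (metric, mode), sub in sin.groupby(["metric", "weight_mode"]):
        measures[f"sin_z::{metric}::{mode}"] = _by_genotype(sub, "z")
    act = pd.read_csv(ROOT / "activity_summary.csv")
    measures["activity::light_mean"] = _by_genotype(act, "light_mean_per_min")
    measures["activity::dark_mean"] = _by_genotype(act, "dark_mean_per_min")
    slp = pd.read_csv(ROOT / "sleep_summary.csv")
    measures["sleep::day_min"] = _by_genotype(slp, "day_sleep_min")
    per = pd.read_csv(ROOT / "circadian_period.csv")
    measures["circadian::period_h"] = _by_genotype(per, "period_h")
    geo = pd.read_csv(ROOT / "geotaxis_groups.csv")
    measures["geotaxis::score_pct"] = _by_genotype(geo, "score_pct")
    red = pd.read_csv(ROOT / "redox_results.csv")
    measures["redox::free_gsh_uM"] = _by_genotype(red, "free_gsh")
    measures["redox::gssg_uM"] = _by_genotype(red, "gssg")

    policy = StatsPolicy()
    rows = []
    for measure, by_group in sorted(measures.items()):
        comp = choose_and_test(by_group, policy, measure=measure)
        rows.extend(_comparison_rows(comp))
        flag = "*" if (comp.omnibus_p < policy.alpha) else " "
        print(f"{flag} {measure}: {comp.omnibus_test} p = {comp.omnibus_p:.2g}")
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "group_comparisons.csv", index=False, float_format="%.12g")
    print(f"wrote {ROOT / 'group_comparisons.csv'} ({len(out)} rows)")


if __name__ == "__main__":
    main()
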