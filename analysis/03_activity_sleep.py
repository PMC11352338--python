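#!/usr/bin/env python
"""Locomotor activity, sleep and circadian period per genotype.

Reads the 5-day light/dark and constant-darkness beam-break series from
results/data/, computes per-fly day/night activity means, daily sleep
minutes (inactivity > 5 min), and the free-running period (chi-square
periodogram).  Writes results/activity_summary.csv, results/sleep_summary.csv
and results/circadian_period.csv.
"""

from pathlib import Path

import pandas as pd

from flysin.activity import (detect_sleep, estimate_period, phase_summary, read_monitor,
                             sleep_by_phase)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    act_rows, sleep_rows, period_rows = [], [], []
    for p in sorted((ROOT / "data").glob("activity_*.csv")):
        dd = p.stem.startswith("activity_dd_")
        genotype = p.stem.replace("activity_dd_", "").replace("activity_", "")
        series = read_monitor(p, constant_darkness=dd)
        for s in series:
            if dd:
                est = estimate_period(s)
                period_rows.append({"genotype": genotype, "fly": s.fly_id,
                                    "period_h": est.period_h,
                                    "statistic": est.statistic,
                                    "significant": est.significant})
            else:
                tab = sleep_by_phase(s, detect_sleep(s))
                act_rows.append({"genotype": genotype, "fly": s.fly_id,
                                 "light_mean_per_min": phase_summary(s, "light"),
                                 "dark_mean_per_min": phase_summary(s, "dark")})
                sleep_rows.append({"genotype": genotype, "fly": s.fly_id,
                                   "day_sleep_min":
                                       tab[tab.phase == "light"]["sleep_min"].mean(),
                                   "night_sleep_min":
                                       tab[tab.phase == "dark"]["sleep_min"].mean()})
    act = pd.DataFrame(act_rows)
    slp = pd.DataFrame(sleep_rows)
    per = pd.DataFrame(period_rows)
    act.to_csv(ROOT / "activity_summary.csv", index=False, float_format="%.12g")
    slp.to_csv(ROOT / "sleep_summary.csv", index=False, float_format="%.12g")
    per.to_csv(ROOT / "circadian_period.csv", index=False, float_format="%.12g")
    for genotype, sub in act.groupby("genotype"):
        ps = per[per.genotype == genotype]
        print(f"{genotype}: day activity {sub.light_mean_per_min.mean():.2f}/min, "
              f"night {sub.dark_mean_per_min.mean():.2f}/min, "
              f"period {ps.period_h.mean():.2f} h")


if __name__ == "__main__":
    main()
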