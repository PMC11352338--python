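#!/usr/bin/env python
"""Negative-geotaxis scoring: percent of flies climbing 5 cm within 5 s.

Aggregates the trial table from results/data/geotaxis.csv into group scores
(mean over a group's five trials) and genotype summaries (mean +/- SEM over
groups).  Writes results/geotaxis_groups.csv and results/geotaxis_summary.csv.
"""

from pathlib import Path

from flysin.geotaxis import aggregate, read_trials

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(ROOT / "data" / "geotaxis.csv")
    groups, summary = aggregate(trials, scheme="group")
    groups.to_csv(ROOT / "geotaxis_groups.csv", index=False, float_format="%.12g")
    summary.to_csv(ROOT / "geotaxis_summary.csv", index=False, float_format="%.12g")
    for _, row in summary.iterrows():
        print(f"{row.genotype}: {row.mean_pct:.1f} +/- {row.sem_pct:.1f} % climbed "
              f"(n={row.n_units} groups)")


if __name__ == "__main__":
    main()
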