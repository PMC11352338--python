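#!/usr/bin/env python
"""Generate the synthetic study cohort all later analysis steps consume.

Three genotypes (a control and two transgenic-like lines) differing in
social attraction, locomotor rate and climbing ability, plus glutathione
assay plates.  Writes plain-text raw data under results/data/:

* trajectories/<genotype>_r<k>.csv — arena trajectory tables (12 flies, 60 s)
* activity_<genotype>.csv          — 5-day per-minute beam-break series
* activity_dd_<genotype>.csv       — 5-day constant-darkness series
* geotaxis.csv                     — climbing trials (5 groups x 5 trials)
* assay_<genotype>.csv             — Ellman A415 reads + calibration
"""

from pathlib import Path

import pandas as pd

from flysin import synthetic as syn
from flysin.activity import write_activity_csv
from flysin.geotaxis import write_trials
from flysin.trajectory_io import write_trajectories

SEED = 20_240_801
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

# planted ground truth: the "2nd"/"3rd" lines are less social, less active,
# poorer climbers, with depleted GSH but unchanged GSSG
GENOTYPES = {
    "w1118":   dict(attraction=0.30, counts_per_min=2.0, period_h=24.0,
                    p_climb=0.80, gsh_uM=8.0, gssg_uM=2.0),
    "line2nd": dict(attraction=0.00, counts_per_min=1.4, period_h=23.4,
                    p_climb=0.75, gsh_uM=5.0, gssg_uM=2.0),
    "line3rd": dict(attraction=0.00, counts_per_min=1.5, period_h=24.0,
                    p_climb=0.55, gsh_uM=5.0, gssg_uM=2.0),
}
N_RECORDINGS = 8
N_FLIES = 12


def main() -> None:
    (OUT / "trajectories").mkdir(parents=True, exist_ok=True)
    arena = syn.ArenaSpec(duration_s=60.0)
    geo_tabs = []
    for gi, (genotype, truth) in enumerate(sorted(GENOTYPES.items())):
        base = SEED + 10_000 * gi
        profile = syn.SocialProfile(attraction_strength=truth["attraction"])
        for r in range(N_RECORDINGS):
            tracks = syn.simulate_trajectories(arena, N_FLIES, profile, seed=base + r)
            write_trajectories(tracks, OUT / "trajectories" / f"{genotype}_r{r}.csv")

        prof = syn.ActivityProfile(mean_counts_per_min=truth["counts_per_min"],
                                   period_h=truth["period_h"])
        ld = [syn.simulate_activity(prof, 5, seed=base + 100 + f, fly_id=f)
              for f in range(8)]
        write_activity_csv(ld, OUT / f"activity_{genotype}.csv")
        dd = [syn.simulate_activity(prof, 5, seed=base + 200 + f,
                                    constant_darkness=True, fly_id=f)
              for f in range(8)]
        write_activity_csv(dd, OUT / f"activity_dd_{genotype}.csv")

        geo_tabs.append(syn.simulate_geotaxis(truth["p_climb"], 5, 10, 5,
                                              seed=base + 300, genotype=genotype))

        plates = [syn.simulate_assay_readings(truth["gsh_uM"], truth["gssg_uM"],
                                              noise_sd=0.003, seed=base + 400 + k,
                                              sample_id=f"{genotype}_{k}")
                  for k in range(9)]
        pd.concat(plates, ignore_index=True).to_csv(OUT / f"assay_{genotype}.csv",
                                                    index=False)
    write_trials(pd.concat(geo_tabs, ignore_index=True), OUT / "geotaxis.csv")
    print(f"wrote cohort for {len(GENOTYPES)} genotypes "
          f"({N_RECORDINGS} recordings x {N_FLIES} flies each) under {OUT}")


if __name__ == "__main__":
    main()
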