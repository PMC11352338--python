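#!/usr/bin/env python
"""Glutathione concentrations from the Ellman-assay plates.

Fits each genotype's A415 calibration line, back-calculates free and total
glutathione per sample, and derives GSSG = (total - free)/2.  Writes
results/redox_results.csv.
"""

from pathlib import Path

import pandas as pd

from flysin.redox import analyze_assay_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tabs = []
    for p in sorted((ROOT / "data").glob("assay_*.csv")):
        genotype = p.stem.replace("assay_", "")
        out = analyze_assay_table(pd.read_csv(p))
        out.insert(0, "genotype", genotype)
        tabs.append(out)
    res = pd.concat(tabs, ignore_index=True)
    res.to_csv(ROOT / "redox_results.csv", index=False, float_format="%.12g")
    for genotype, sub in res.groupby("genotype"):
        print(f"{genotype}: GSH {sub.free_gsh.mean():.2f} uM, "
              f"GSSG {sub.gssg.mean():.2f} uM (n={len(sub)})")


if __name__ == "__main__":
    main()
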