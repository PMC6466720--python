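"""Derive growth, FCR and isotope indicator phenotypes.

Applies the growth filters (relative gain < 6.4% or > 49% set missing),
computes APE over baseline, the IFCR/IFER indicator ratios for muscle N
and C, tank FCR and tank means.  Writes a descriptive-statistics table
(one row per trait) to results/.
"""

import json

import pandas as pd

from common import CONFIG, RESULTS, RUN_DIR
from isofeed.pipeline import run_pipeline

run_pipeline(CONFIG, RUN_DIR, stages=["derive"])
ind = pd.read_csv(RUN_DIR / "derived_individuals.tsv", sep="\t")
tanks = pd.read_csv(RUN_DIR / "derived_tanks.tsv", sep="\t")
counts = json.loads((RUN_DIR / "filter_counts.json").read_text())

traits = ["iw", "fw", "wg", "rg", "atom_amc", "atom_amn", "atom_alc",
          "atom_aln", "atom_aac", "ifcr_amn", "ifer_amn"]
rows = []
for t in traits:
    v = ind.loc[~ind["growth_missing"], t]
    rows.append({"trait": t, "mean": v.mean(), "sd": v.std(),
                 "min": v.min(), "max": v.max(),
                 "cv_pct": 100 * v.std() / abs(v.mean())})
rows.append({"trait": "fcr(tank)", "mean": tanks["fcr"].mean(),
             "sd": tanks["fcr"].std(), "min": tanks["fcr"].min(),
             "max": tanks["fcr"].max(),
             "cv_pct": 100 * tanks["fcr"].std() / tanks["fcr"].mean()})
desc = pd.DataFrame(rows)
desc.to_csv(RESULTS / "02_descriptive_stats.tsv", sep="\t", index=False)

print(desc.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\nfiltered: {counts['low_growth']} low-growth, "
      f"{counts['high_growth']} high-growth, "
      f"{counts['weight_missing']} missing weights "
      f"({100 * counts['total_missing'] / len(ind):.1f}% of fish)")
print(f"tank FCR mean {tanks['fcr'].mean():.3f} "
      f"(CV {100 * tanks['fcr'].std() / tanks['fcr'].mean():.1f}%)")
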