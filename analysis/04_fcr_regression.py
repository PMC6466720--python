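"""Tank-level regression of FCR on day and indicator-trait tank means.

Reproduces the per-covariate scan (R2, adjusted R2, predictive R2hat,
bias, PRESS, one covariate at a time alongside sampling day) and the
PRESS-minimizing backward elimination over all candidates.
"""

import json

import pandas as pd

from common import CONFIG, RESULTS, RUN_DIR
from isofeed.pipeline import run_pipeline

run_pipeline(CONFIG, RUN_DIR, stages=["regress"])
scan = pd.read_csv(RUN_DIR / "regression_scan.tsv", sep="\t")
selected = json.loads((RUN_DIR / "regression_selected.json").read_text())
trace = pd.read_csv(RUN_DIR / "regression_elimination.tsv", sep="\t")

scan.to_csv(RESULTS / "04_fcr_regression_scan.tsv", sep="\t", index=False)
trace.to_csv(RESULTS / "04_fcr_elimination_trace.tsv", sep="\t", index=False)

print("single-covariate scan (each + sampling day):")
print(scan.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\nbackward elimination kept: {selected['selected']}")
print(f"R2 {selected['r2']:.2f}, predictive R2hat {selected['r2_hat']:.2f}, "
      f"PRESS {selected['press']:.4g}, leave-one-out bias {selected['bias_loo']:.2e}")
best_single = scan.sort_values("r2_hat", ascending=False).iloc[0]
print(f"best single covariate by R2hat: {best_single['covariate']} "
      f"({best_single['r2_hat']:.2f})")
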