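"""REML variance components, heritabilities and genetic correlations.

Fits the tank-level model (genetic tank effect with G_T, diagonal
residual) to FCR/FI pairs and the individual model (genomic + tank +
residual) to individual traits, reports variance ratios (h_t2, h2, c2),
likelihood-ratio tests of the genetic term, and genetic/phenotypic
correlations per pair.
"""

import pandas as pd

from common import CONFIG, RESULTS, RUN_DIR
from isofeed.pipeline import run_pipeline

run_pipeline(CONFIG, RUN_DIR, stages=["fit"])
comp = pd.read_csv(RUN_DIR / "variance_components.tsv", sep="\t")
corr = pd.read_csv(RUN_DIR / "genetic_correlations.tsv", sep="\t")
comp.to_csv(RESULTS / "05_variance_components.tsv", sep="\t", index=False)
corr.to_csv(RESULTS / "05_genetic_correlations.tsv", sep="\t", index=False)

print("per-trait variance components and ratios:")
cols = [c for c in ("trait", "level", "genetic_var1", "tank_var1",
                    "residual_var1", "ht2", "h2", "c2", "lr", "p") if c in comp]
print(comp[cols].to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print("\ntrait-pair genetic and phenotypic correlations:")
cols = ["trait1", "trait2", "level", "r_genetic", "r_phenotypic", "rg_boundary"]
print(corr[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
sig = comp.loc[comp["p"] < 0.05, "trait"].tolist()
print(f"\ngenetic term significant (LR test, chi2 df=1, alpha=0.05) for: {sig}")
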