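"""Generate a small synthetic multiphase-CT cohort and inspect it.

Builds a 12-subject cohort (8 ccRCC / 2 pRCC / 2 cRCC) on 24^3 grids,
prints the per-subtype mean lesion attenuation in each phase, and shows
the head of the clinical covariate table.  The phase attenuation
profiles should track the configured per-subtype medians (e.g. ccRCC
CMP near 105 HU, pRCC CMP near 54 HU) up to between-subject spread.
"""

import pandas as pd

from rcc_radiomics import CohortConfig, generate_clinical_table, generate_cohort

cfg = CohortConfig(
    counts={"ccRCC": 8, "pRCC": 2, "cRCC": 2}, shape=(24, 24, 24), seed=7
)
cohort = generate_cohort(cfg)
table = generate_clinical_table(cohort)

print(f"cohort: {len(cohort)} subjects, grid {cfg.shape}, seed {cfg.seed}\n")
att_cols = ["att_ncp", "att_cmp", "att_np", "att_ep"]
print("mean lesion attenuation (HU) by subtype and phase:")
print(table.groupby("subtype")[att_cols].mean().round(1))
print("\nclinical table (first rows):")
with pd.option_context("display.width", 120):
    print(table.drop(columns=att_cols).head(5))
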