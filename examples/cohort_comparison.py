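"""End-to-end cohort pipeline: simulate, extract, compare, summarize.

Samples small WT and fmr1-KO cohorts of both projection classes, extracts a
compact feature battery per cell, runs the genotype comparisons with
Bonferroni correction within declared families, and prints the direction
summary (the arrow table of the channelopathy phenotype).
"""

import warnings

warnings.filterwarnings("ignore")

from fxsephys import cohort

config = {
    "n_cells": 6,
    "classes": ("PT", "IT"),
    "features": {
        "PT": ("sag", "f_R", "summation", "RMP", "I_h_max",
               "I_KA_fast_peak", "I_K_slow_peak"),
        "IT": ("sag", "f_R", "summation", "RMP"),
    },
    "families": {
        "PT": {
            "subthreshold": ("sag", "f_R", "summation", "RMP"),
            "vclamp": ("I_h_max", "I_KA_fast_peak", "I_K_slow_peak"),
        },
        "IT": {"subthreshold": ("sag", "f_R", "summation", "RMP")},
    },
    "step_amplitudes_pA": tuple(range(-150, 11, 20)),
}

result = cohort.run_pipeline(config, seed=7)

print(f"{'class':5s} {'feature':16s} {'WT mean':>9s} {'KO mean':>9s} "
      f"{'p_adj':>8s} {'KO vs WT':>9s}")
for comp, cls in result.comparisons:
    d = result.summary.directions[(comp.feature, cls)]
    arrow = {"up": "up", "down": "down", "unchanged": "-"}[d]
    print(f"{cls:5s} {comp.feature:16s} {comp.means['WT']:9.2f} "
          f"{comp.means['KO']:9.2f} {comp.p_adjusted:8.4f} {arrow:>9s}")

print()
print("PT neurons carry the channelopathy (h-current and Kv1-like current")
print("down, Kv4-like current up, more summation); IT neurons show only the")
print("hyperpolarized resting potential.")
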