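"""Group comparisons with the reported conventions.

Two groups: two-tailed Student t-test. Three or more: one-way ANOVA with
Tukey's HSD post hoc test. Stars: ns p>=0.05, * <0.05, ** <0.01,
*** <0.001, **** <0.0001.
"""
import numpy as np

import fociquant as fq
from fociquant.stats import results_table

rng = np.random.default_rng(0)
groups = {
    "WT":    rng.normal(1.00, 0.25, 60),   # normalized nuclear F-actin
    "L229P": rng.normal(1.60, 0.30, 50),   # constitutively active: elevated
    "V418fs": rng.normal(0.85, 0.20, 55),  # truncation: slightly reduced
}

print(results_table(fq.anova_tukey(groups)).to_string(index=False))

t = fq.two_tailed_t(groups["WT"], groups["L229P"])
print(f"\nWT vs L229P alone: t = {t.statistic:.2f}, p = {t.p_value:.2e} {t.stars}")
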