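"""Arthritic-versus-control statistics on roughness scores.

Computes the roughness ratio mu_AR/CO with its propagated uncertainty,
a percentile-bootstrap confidence interval of the ratio, the CI-non-overlap
significance decision, and the rank tests (Mann-Whitney U, Spearman).
"""

import numpy as np

from osteorough.groupstats import compare_groups, rank_tests

rng = np.random.default_rng(0)
R_arthritic = rng.normal(0.060, 0.012, 8)  # e.g. R_cs at r=3, day 18
R_control = rng.normal(0.028, 0.006, 8)

cmp_ = compare_groups(R_arthritic, R_control, metric="R_cs_r3",
                      n_boot=10000, seed=42)
print(f"mu_AR = {cmp_.mu_AR:.4f} +/- {cmp_.sigma_AR:.4f}")
print(f"mu_CO = {cmp_.mu_CO:.4f} +/- {cmp_.sigma_CO:.4f}")
print(f"ratio mu_AR/CO = {cmp_.mu_ratio:.3f} +/- {cmp_.sigma_ratio:.3f} "
      f"(95% bootstrap CI [{cmp_.ci_low:.3f}, {cmp_.ci_high:.3f}])")
print(f"group-mean CIs disjoint -> significant: {cmp_.significant}")

u, p = rank_tests(R_arthritic, R_control)
print(f"Mann-Whitney U = {u:.0f}, two-tailed p = {p:.4g}")

score = np.arange(8) + rng.normal(0, 0.5, 8)  # clinical score rising with R
rho, p = rank_tests(score, np.sort(R_arthritic), method="spearman")
print(f"Spearman rho = {rho:.2f} (p = {p:.3g}) between score and roughness")
# A ratio near 2 with a CI excluding the control band mirrors how arthritic
# erosion roughly doubles surface roughness relative to healthy bones.
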