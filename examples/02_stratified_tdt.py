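"""HLA-stratified TDT with the weighted chi-square ranking statistic.

Offspring homozygous for the risk allele of a designated "HLA-like" locus
form the high-risk stratum; the remainder are low-risk.  Each stratum gets
its own TDT and markers are ranked by the pooled weighted chi-square
sum_g (T_g - U_g)^2 / sum_g (T_g + U_g), which rewards markers whose signal
is concentrated in one stratum.
"""

import numpy as np

from triogwas import (PenetranceSpec, SimulationConfig, TransmissionCounts,
                      simulate_families, stratified_scan, weighted_chisq)

cfg = SimulationConfig(
    n_families=200,
    freqs=np.full(6, 0.4),
    disease_model=[PenetranceSpec("single_locus_grr", (0,),
                                  {"baseline": 0.04, "grr": 2.5})],
    stratification_locus=5,
    seed=11,
)
data = simulate_families(cfg)
res = stratified_scan(data)

print(res[["id", "T_high", "U_high", "T_low", "U_low", "weighted_chisq"]]
      .head(3).to_string(index=False))

# the statistic on a published-style pair of stratum counts:
w = weighted_chisq([TransmissionCounts(26, 35), TransmissionCounts(87, 28)])
print(f"\nweighted chisq for strata (T=26,U=35) and (T=87,U=28): {w:.2f}")
print("A large value driven by the low-risk stratum flags risk factors that")
print("matter most for children without the primary HLA risk genotype.")
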