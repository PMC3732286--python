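"""Two-locus interaction test on a planted epistatic pair.

500 ascertained families are simulated with a penetrance elevated only when
a child carries risk alleles at BOTH loci (0.30 vs 0.02 baseline).  One
affected child per family contributes its joint genotype to the case table
n; the un-transmitted parental alleles form the matched pseudo-control
table m.  Four penetrance models are fitted by maximum likelihood and
compared by likelihood-ratio tests.
"""

import numpy as np

from triogwas import (PenetranceSpec, SimulationConfig, fit_model, lrt,
                      simulate_families, tabulate_two_locus)

cfg = SimulationConfig(
    n_families=500,
    freqs=np.array([0.3, 0.3]),
    disease_model=[PenetranceSpec("epistatic_cell", (0, 1),
                                  {"baseline": 0.02, "cell": 0.3})],
    seed=3,
)
data = simulate_families(cfg)
F, M, C = data.trio_genotypes()
first = data.trios[data.trios["affected"]].groupby("fid").head(1).index.to_numpy()
tables = tabulate_two_locus(F[first, 0], M[first, 0], C[first, 0],
                            F[first, 1], M[first, 1], C[first, 1])
print("case table n (rows = A1 copies at locus A):")
print(tables.n)

fits = {m: fit_model(m, tables, seed=3) for m in ("M0", "MR", "MM", "MG")}
for name, fit in fits.items():
    print(f"{name}: loglik = {fit.loglik:9.2f}  allele freqs = "
          f"({fit.allele_freqs[0]:.3f}, {fit.allele_freqs[1]:.3f})")

p_02 = lrt(fits["M0"], fits["MG"])   # 8 df: any association at all?
p_12 = lrt(fits["MR"], fits["MG"])   # 3 df: beyond heterogeneity?
p_m2 = lrt(fits["MM"], fits["MG"])   # 4 df: beyond multiplicative?
print(f"\nP_02 = {p_02:.2e}   P_12 = {p_12:.2e}   P_M2 = {p_m2:.2e}")
print("Small P_02 says the pair is associated; small P_M2 rules out the")
print("multiplicative model expected when one locus is a false positive; and")
print("small P_12 rejects independent-cause heterogeneity, leaving epistasis —")
print("the planted joint-carrier effect.")
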