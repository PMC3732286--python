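import numpy as np
import pandas as pd
import pytest

from triogwas.simulate import PenetranceSpec, SimulationConfig, simulate_families

#: canonical planted two-locus effects used across tests
EPISTATIC = PenetranceSpec("epistatic_cell", (0, 1), {"baseline": 0.02, "cell": 0.3})
HETEROGENEITY = PenetranceSpec("heterogeneity", (0, 1),
                               {"alpha": [0.01, 0.25, 0.25], "beta": [0.01, 0.25, 0.25]})
NULL_MODEL = [PenetranceSpec("constant", params={"value": 0.5})]


def random_consistent_trio(rng):
    """One Mendelian-consistent fully typed trio by forward transmission."""
    fa = rng.integers(0, 2, size=2).sum()
    mo = rng.integers(0, 2, size=2).sum()
    # child receives a uniformly chosen allele from each parent's unordered pair
    f_alleles = [1] * fa + [0] * (2 - fa)
    m_alleles = [1] * mo + [0] * (2 - mo)
    child = f_alleles[rng.integers(0, 2)] + m_alleles[rng.integers(0, 2)]
    return int(fa), int(mo), int(child)


def null_two_locus_tables(seed, n_families=100, freqs=(0.5, 0.4)):
    """Case/pseudo-control tables from an ascertained null simulation."""
    from triogwas.interaction import tabulate_two_locus
    cfg = SimulationConfig(n_families=n_families, freqs=np.array(freqs),
                           disease_model=NULL_MODEL, seed=seed)
    data = simulate_families(cfg)
    F, M, C = data.trio_genotypes()
    sel = data.trios[data.trios["affected"]].groupby("fid").head(1).index.to_numpy()
    return tabulate_two_locus(F[sel, 0], M[sel, 0], C[sel, 0],
                              F[sel, 1], M[sel, 1], C[sel, 1])


def planted_pair_tables(spec, seed, n_families=500, freqs=(0.3, 0.3)):
    from triogwas.interaction import tabulate_two_locus
    cfg = SimulationConfig(n_families=n_families, freqs=np.array(freqs),
                           disease_model=[spec], seed=seed)
    data = simulate_families(cfg)
    F, M, C = data.trio_genotypes()
    sel = data.trios[data.trios["affected"]].groupby("fid").head(1).index.to_numpy()
    return tabulate_two_locus(F[sel, 0], M[sel, 0], C[sel, 0],
                              F[sel, 1], M[sel, 1], C[sel, 1])


def write_dataset(out_dir, n_families=80, seed=0, noise=0.02, disease_model=None):
    """Write a small synthetic study to disk: an ascertained panel with one
    single-locus risk variant (locus 0), one epistatic pair (loci 3, 4), a
    stratification locus (locus 9) and nulls elsewhere, plus the companion
    strata and external tables.  Returns the pipeline input config dict."""
    from pathlib import Path

    from triogwas.simulate import (blur_posteriors, make_external_table,
                                   simulate_families)
    from triogwas.trio_data import write_gen, write_sample
    from triogwas.pipeline import _write_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        n_families=n_families,
        freqs=np.full(10, 0.3),
        positions=200_000 * (1 + np.arange(10)),
        disease_model=disease_model if disease_model is not None else [
            PenetranceSpec("single_locus_grr", (0,), {"baseline": 0.05, "grr": 3.0}),
            PenetranceSpec("epistatic_cell", (3, 4), {"baseline": 0.02, "cell": 0.3}),
        ],
        stratification_locus=9,
        seed=seed)
    data = simulate_families(cfg)
    post = blur_posteriors(data.genotypes, noise, rng=seed + 1)
    with open(out / "families.fam", "w") as fh:
        for _, s in data.samples.iterrows():
            fh.write(f"{s['fid']} {s['iid']} {s['father']} {s['mother']} "
                     f"{s['sex']} {s['phenotype']}\n")
    write_sample(out / "families.sample", data.samples)
    write_gen(out / "genotypes.gen", data.markers, post)
    _write_tsv(data.trios[["fid", "iid", "stratum"]], out / "strata.tsv")
    _write_tsv(make_external_table(data.markers, {"snp0": 1}, rng=seed + 2),
               out / "external.tsv")
    return {"pedigree": str(out / "families.fam"),
            "gen": str(out / "genotypes.gen"),
            "sample": str(out / "families.sample"),
            "strata": str(out / "strata.tsv"),
            "external": str(out / "external.tsv")}


@pytest.fixture
def small_pedigree(tmp_path):
    """Two families: an affected sib pair and a child with a missing father."""
    path = tmp_path / "ped.fam"
    path.write_text(
        "f1 dad 0 0 1 1\n"
        "f1 mum 0 0 2 1\n"
        "f1 kid1 dad mum 0 2\n"
        "f1 kid2 dad mum 0 2\n"
        "f2 solo 0 mumX 0 2\n"
        "f2 mumX 0 0 2 1\n"
    )
    return path


@pytest.fixture
def gene_table():
    starts = [100_000, 200_000, 300_000, 400_000, 500_000, 600_000]
    return pd.DataFrame({
        "chrom": ["1"] * 7 + ["2"],
        "start": starts + [5_000_000, 100],
        "end": [s + 50_000 for s in starts] + [5_050_000, 200],
        "name": ["G1", "G2", "G3", "G4", "G5", "G6", "FAR", "OTHER"],
    })
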