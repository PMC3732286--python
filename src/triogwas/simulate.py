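"""Seeded generator of ascertained nuclear families and companion inputs.

The generator emulates the study design every pipeline stage assumes:
nuclear families with two parents and (by default) two offspring, retained
only when at least a configured number of offspring are affected (the
affected-sib-pair ascertainment).  Parental genotypes are drawn from
Hardy-Weinberg equilibrium independently per locus (no linkage
disequilibrium), offspring receive one uniformly chosen allele from each
parent, and affection status is Bernoulli with a penetrance computed from
the offspring's genotypes at the configured risk loci.  All remaining loci
are pure nulls.

Also provided: a posterior "blur" that turns true genotypes into
imputation-style probability triplets, a stand-in external association
table for the replication criterion, and a synthetic qPCR Ct table.

Everything is driven by a single integer seed; a given seed reproduces
every artifact bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trio_data import FamilyData, build_trios

#: Posterior-noise level at which about 88% of true-genotype posteriors
#: exceed the 0.95 hard-call threshold (the regime of well-imputed panels):
#: with blur posterior (1-l) + l*d, d ~ Beta(1, 2), the exceedance
#: probability is (0.05/l)^2 for l >= 0.05, giving ~0.89 at l = 0.053.
DEFAULT_POSTERIOR_NOISE = 0.053


@dataclass(frozen=True)
class PenetranceSpec:
    """Penetrance contribution of one risk locus or locus pair.

    kind:
      * "constant": params ``value``; genotype-independent.
      * "single_locus_grr": params ``baseline``, ``grr``; one locus,
        f = baseline * grr**dosage (capped below 1).
      * "multiplicative": params ``alpha`` (3,), ``beta`` (3,); locus pair,
        f_ij = alpha_i * beta_j.
      * "heterogeneity": params ``alpha``, ``beta``; locus pair,
        f_ij = 1 - (1-alpha_i)(1-beta_j).
      * "epistatic_cell": params ``baseline``, ``cell``; locus pair,
        f = cell when both loci carry a risk allele, baseline otherwise.
      * "matrix": params ``f`` explicit 3x3; locus pair.
    """

    kind: str
    loci: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)

    def penetrance(self, child_genotypes: np.ndarray) -> np.ndarray:
        """Per-child penetrance from (n_children, n_loci) dosage matrix."""
        p = self.params
        if self.kind == "constant":
            return np.full(child_genotypes.shape[0], float(p["value"]))
        if self.kind == "single_locus_grr":
            g = child_genotypes[:, self.loci[0]]
            return np.minimum(p["baseline"] * np.asarray(p["grr"]) ** g, 1.0 - 1e-9)
        ga = child_genotypes[:, self.loci[0]]
        gb = child_genotypes[:, self.loci[1]]
        if self.kind == "multiplicative":
            return np.asarray(p["alpha"])[ga] * np.asarray(p["beta"])[gb]
        if self.kind == "heterogeneity":
            return 1.0 - (1.0 - np.asarray(p["alpha"])[ga]) * (1.0 - np.asarray(p["beta"])[gb])
        if self.kind == "epistatic_cell":
            both = (ga >= 1) & (gb >= 1)
            return np.where(both, float(p["cell"]), float(p["baseline"]))
        if self.kind == "matrix":
            return np.asarray(p["f"], dtype=float)[ga, gb]
        raise ValueError(f"unknown penetrance kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Conditions of a simulated affected-sib-pair study.

    Defaults mirror the study design the package targets: 97 nuclear
    families, two offspring each, both required affected for ascertainment,
    and posterior noise at the well-imputed regime.
    """

    n_families: int = 97
    n_offspring: int = 2
    min_affected: int = 2
    freqs: np.ndarray = field(default_factory=lambda: np.full(20, 0.3))
    chroms: list | None = None
    positions: np.ndarray | None = None
    disease_model: list = field(default_factory=lambda: [PenetranceSpec("constant", params={"value": 0.02})])
    stratification_locus: int | None = None
    posterior_noise: float = DEFAULT_POSTERIOR_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any((self.freqs <= 0) | (self.freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        L = len(self.freqs)
        if self.positions is None:
            self.positions = 1_000_000 * (1 + np.arange(L))
        if self.chroms is None:
            self.chroms = ["1"] * L


def marker_table(config: SimulationConfig) -> pd.DataFrame:
    L = len(config.freqs)
    return pd.DataFrame({
        "id": [f"snp{i}" for i in range(L)],
        "chrom": [str(c) for c in config.chroms],
        "bp": np.asarray(config.positions, dtype=int),
        "a1": ["A"] * L,
        "a2": ["G"] * L,
    })


def _penetrance_of(config: SimulationConfig, child_geno: np.ndarray) -> np.ndarray:
    """Combine disease-model components as independent causes: 1 - prod(1 - f_k)."""
    keep = np.ones(child_geno.shape[0])
    for spec in config.disease_model:
        keep *= 1.0 - spec.penetrance(child_geno)
    return 1.0 - keep


def simulate_families(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> FamilyData:
    """Generate an ascertained family panel with true genotypes.

    Families are simulated in vectorized batches and kept only when at least
    ``min_affected`` offspring are affected, until ``n_families`` have been
    retained.  Raises ``RuntimeError`` when the expected ascertainment yield
    falls below one family per million attempts.

    The returned :class:`FamilyData` carries hard genotypes (the error-free
    truth), a trio table with one row per offspring, and — when a
    stratification locus is configured — a ``stratum`` column set to "high"
    for offspring homozygous for that locus's risk (A1) allele.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = len(config.freqs)
    k = config.n_offspring
    kept_fa, kept_mo, kept_ch, kept_aff = [], [], [], []
    kept = 0
    attempts = 0
    batch = max(256, 4 * config.n_families)
    while kept < config.n_families:
        fa_alleles = (rng.random((batch, L, 2)) < config.freqs[None, :, None]).astype(np.int8)
        mo_alleles = (rng.random((batch, L, 2)) < config.freqs[None, :, None]).astype(np.int8)
        pick_f = rng.integers(0, 2, size=(batch, k, L))
        pick_m = rng.integers(0, 2, size=(batch, k, L))
        child = (np.take_along_axis(fa_alleles, pick_f.transpose(0, 2, 1), axis=2).transpose(0, 2, 1)
                 + np.take_along_axis(mo_alleles, pick_m.transpose(0, 2, 1), axis=2).transpose(0, 2, 1))
        f = _penetrance_of(config, child.reshape(batch * k, L)).reshape(batch, k)
        affected = rng.random((batch, k)) < f
        ok = affected.sum(axis=1) >= config.min_affected
        attempts += batch
        for b in np.flatnonzero(ok):
            if kept >= config.n_families:
                break
            kept_fa.append(fa_alleles[b].sum(axis=1))
            kept_mo.append(mo_alleles[b].sum(axis=1))
            kept_ch.append(child[b])
            kept_aff.append(affected[b])
            kept += 1
        if attempts >= 1_000_000 and kept == 0:
            raise RuntimeError(
                "ascertainment yield below 1 per 1e6 attempted families; "
                "the configured penetrance is too low for the ascertainment rule")
    rows = []
    geno_rows = []
    for fam in range(config.n_families):
        fid = f"fam{fam}"
        rows.append((fid, "father", "0", "0", "1", "1"))
        geno_rows.append(kept_fa[fam])
        rows.append((fid, "mother", "0", "0", "2", "1"))
        geno_rows.append(kept_mo[fam])
        for c in range(k):
            pheno = "2" if kept_aff[fam][c] else "1"
            rows.append((fid, f"child{c}", "father", "mother", "0", pheno))
            geno_rows.append(kept_ch[fam][c])
    samples = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"])
    samples["affected"] = samples["phenotype"] == "2"
    trios = build_trios(samples)
    geno = np.vstack(geno_rows).astype(np.int8)
    if config.stratification_locus is not None:
        child_g = geno[trios["child_idx"].to_numpy(), config.stratification_locus]
        trios["stratum"] = np.where(child_g == 2, "high", "low")
    return FamilyData(samples=samples, trios=trios, markers=marker_table(config),
                      genotypes=geno)


def blur_posteriors(genotypes: np.ndarray, noise: float,
                    rng: np.random.Generator | int = 0) -> np.ndarray:
    """Imputation-style posterior triplets from true genotypes.

    posterior = (1 - noise) * onehot(truth) + noise * Dirichlet(1,1,1);
    noise = 0 reproduces certain posteriors and noise = 1 pure Dirichlet
    draws (which almost never clear a 0.95 hard-call threshold).
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, L = genotypes.shape
    onehot = np.zeros((n, L, 3))
    valid = genotypes >= 0
    idx = np.clip(genotypes, 0, 2)
    np.put_along_axis(onehot, idx[..., None].astype(np.intp), 1.0, axis=2)
    d = rng.dirichlet([1.0, 1.0, 1.0], size=(n, L))
    post = (1.0 - noise) * onehot + noise * d
    post[~valid] = 1.0 / 3.0
    return post


def make_external_table(markers: pd.DataFrame, replicating: dict,
                        rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Stand-in external association results for the replication criterion.

    ``replicating`` maps SNP id -> direction (+1 risk on A1, -1 protective).
    Designated markers receive small p-values (uniform on 1e-6..1e-4) and an
    odds ratio on the requested side of 1; all others receive p uniform on
    0.05..1 with a random direction, so they fail the external cut.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    recs = []
    for _, mk in markers.iterrows():
        if mk["id"] in replicating:
            p = float(rng.uniform(1e-6, 1e-4))
            orr = 1.6 if replicating[mk["id"]] > 0 else 1 / 1.6
        else:
            p = float(rng.uniform(0.05, 1.0))
            orr = 1.6 if rng.random() < 0.5 else 1 / 1.6
        recs.append((mk["id"], mk["a1"], orr, p))
    return pd.DataFrame(recs, columns=["SNP", "A1", "OR", "p"])


def make_ct_table(n_case: int, n_control: int, targets: dict,
                  reference_genes: list[str] = ("ACTB", "EPCAM", "PGK1"),
                  baseline_dct: float = 5.0, noise_sd: float = 0.5,
                  rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Synthetic long-format qPCR Ct table.

    ``targets`` maps gene -> log2 effect in cases (positive = up-regulated,
    i.e. a lower Ct).  Reference-gene Cts are Normal(20, 0.2) per sample;
    target Ct = sample reference mean + baseline_dct - effect*is_case +
    Normal(0, noise_sd).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    groups = ["case"] * n_case + ["control"] * n_control
    for i, group in enumerate(groups):
        sample = f"{group}{i}"
        ref_cts = rng.normal(20.0, 0.2, size=len(reference_genes))
        for gene, ct in zip(reference_genes, ref_cts):
            rows.append((sample, group, gene, f"{gene}_ref", float(ct)))
        ref_mean = ref_cts.mean()
        for gene, effect in targets.items():
            shift = -effect if group == "case" else 0.0
            ct = ref_mean + baseline_dct + shift + rng.normal(0.0, noise_sd)
            rows.append((sample, group, gene, f"{gene}_assay", float(ct)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "assay", "ct"])
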