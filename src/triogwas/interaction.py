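"""Two-locus gene-gene interaction tests on case/pseudo-control tables.

For each pair of unlinked biallelic markers, one affected offspring per
family contributes its joint genotype to a 3x3 case count matrix ``n``, and
the genotype assembled from the four parental alleles NOT transmitted to
that child (the within-family pseudo-control) contributes to the matching
matrix ``m``.  Indices count copies of the A1 allele at each locus.

Writing ``g_ij = HWE(p_A)_i * HWE(p_B)_j`` for the joint genotype frequency
under Hardy-Weinberg equilibrium and no linkage disequilibrium, and ``f_ij``
for the penetrance of joint genotype (i, j), the log-likelihood of a table
pair is

    l = sum_ij n_ij * log( g_ij f_ij / sum_kl g_kl f_kl )
      + sum_ij m_ij * log( g_ij ).

Four nested penetrance models are fitted by maximum likelihood:

* M0 (no association): f_ij = c constant (2 identifiable parameters);
* MM (multiplicative):  f_ij = alpha_i * beta_j (6);
* MR (heterogeneity):   f_ij = 1 - (1-alpha_i)(1-beta_j) (7);
* MG (general):         9 free penetrances (10; the case distribution
  identifies f only up to scale).

Likelihood-ratio statistics between nested models are referred to
chi-square distributions with df equal to the difference in identifiable
parameter counts: M0-vs-MG 8 df (P_02), MR-vs-MG 3 df (P_12), MM-vs-MG 4 df
(P_M2).  A pair with P_02 below the reporting threshold is classified as
epistasis (small P_12), heterogeneity (large P_12) or
multiplicative-consistent (large P_M2).

M0, MM and MG admit exact maximizers (the case term saturates or factorizes
and the pseudo-control term is a separable HWE fit on the table margins),
so those models are fitted analytically; the heterogeneity model has no
closed form and is fitted by bounded L-BFGS-B with seeded random restarts.
The numeric route is available for every model for cross-checking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trio_data import mendelian_consistent

logger = logging.getLogger(__name__)

MODELS = ("M0", "MR", "MM", "MG")
#: identifiable parameter counts per model
N_PARAMS = {"M0": 2, "MM": 6, "MR": 7, "MG": 10}
PEN_LO, PEN_HI = 1e-6, 1.0 - 1e-6
FREQ_LO, FREQ_HI = 1e-3, 1.0 - 1e-3


@dataclass(frozen=True)
class TwoLocusTables:
    """Paired 3x3 genotype count matrices for cases (n) and pseudo-controls (m)."""

    n: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        m = np.asarray(self.m)
        if n.shape != (3, 3) or m.shape != (3, 3):
            raise ValueError("tables must be 3x3")
        if (n < 0).any() or (m < 0).any():
            raise ValueError("counts must be non-negative")
        if n.sum() != m.sum():
            raise ValueError("case and pseudo-control totals must match")

    @property
    def n_families(self) -> int:
        return int(np.asarray(self.n).sum())


@dataclass
class ModelFit:
    model: str
    allele_freqs: tuple[float, float]
    penetrance: np.ndarray          # the implied 3x3 penetrance matrix
    loglik: float
    converged: bool = True
    n_restarts_used: int = 0


@dataclass(frozen=True)
class InteractionResult:
    snp_a: str
    snp_b: str
    n_families: int
    p_02: float
    p_12: float
    p_m2: float
    classification: str


# ---------------------------------------------------------------------------
# Tables

def pseudo_control_genotype(father: int, mother: int, child: int) -> int:
    """Genotype formed by the parental alleles not transmitted to the child.

    On the A1-dosage scale this is simply ``father + mother - child``; both
    phase resolutions of a double-heterozygote trio give the same genotype.
    """
    if min(father, mother, child) < 0:
        raise ValueError("pseudo-control requires fully typed trios")
    if not mendelian_consistent(father, mother, child):
        raise ValueError("Mendelian-inconsistent trio")
    return int(father + mother - child)


def tabulate_two_locus(FA, MA, CA, FB, MB, CB) -> TwoLocusTables:
    """Build case/pseudo-control tables from per-family genotype vectors.

    Inputs are six equal-length arrays of genotype codes at locus A and
    locus B for the father, mother and the (single) affected child of each
    family.  Families with any missing genotype or a Mendelian inconsistency
    at either locus are skipped.  The pseudo-control genotype is formed per
    locus independently (no linkage disequilibrium is assumed).
    """
    FA, MA, CA, FB, MB, CB = (np.asarray(x) for x in (FA, MA, CA, FB, MB, CB))
    typed = (FA >= 0) & (MA >= 0) & (CA >= 0) & (FB >= 0) & (MB >= 0) & (CB >= 0)
    ok = typed & mendelian_consistent(FA, MA, CA) & mendelian_consistent(FB, MB, CB)
    ca, cb = CA[ok], CB[ok]
    pa, pb = FA[ok] + MA[ok] - ca, FB[ok] + MB[ok] - cb
    n = np.zeros((3, 3), dtype=int)
    m = np.zeros((3, 3), dtype=int)
    np.add.at(n, (ca, cb), 1)
    np.add.at(m, (pa, pb), 1)
    return TwoLocusTables(n, m)


# ---------------------------------------------------------------------------
# Likelihood

def hwe_probs(p: float) -> np.ndarray:
    """Genotype probabilities (0, 1, 2 copies of A1) under HWE at A1 freq p."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def loglik(p_a: float, p_b: float, f: np.ndarray, tables: TwoLocusTables) -> float:
    """Joint log-likelihood of case and pseudo-control tables.

    Returns -inf when a cell with observations has zero genotype frequency.
    """
    g = np.outer(hwe_probs(p_a), hwe_probs(p_b))
    f = np.asarray(f, dtype=float)
    gf = g * f
    s = gf.sum()
    obs = (tables.n + tables.m) > 0
    if s <= 0 or np.any((g <= 0) & obs):
        return -np.inf
    with np.errstate(divide="ignore"):
        case = np.where(tables.n > 0, tables.n * np.log(np.maximum(gf / s, 1e-300)), 0.0)
        ctrl = np.where(tables.m > 0, tables.m * np.log(np.maximum(g, 1e-300)), 0.0)
    return float(case.sum() + ctrl.sum())


def penetrance_matrix(model: str, params) -> np.ndarray:
    """Expand model-specific penetrance parameters into the 3x3 matrix."""
    params = np.asarray(params, dtype=float)
    if model == "M0":
        return np.full((3, 3), params[0])
    if model == "MM":
        return np.outer(params[:3], params[3:6])
    if model == "MR":
        return 1.0 - np.outer(1.0 - params[:3], 1.0 - params[3:6])
    if model == "MG":
        return params.reshape(3, 3)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Closed-form pieces

def _freq_from_margin(margin: np.ndarray) -> float:
    """MLE of the A1 frequency from a genotype-count margin under HWE."""
    tot = margin.sum()
    if tot == 0:
        return 0.5
    p = (margin[1] + 2.0 * margin[2]) / (2.0 * tot)
    return float(np.clip(p, FREQ_LO, FREQ_HI))


def _hwe_margin_loglik(margin: np.ndarray, p: float) -> float:
    probs = hwe_probs(p)
    with np.errstate(divide="ignore"):
        terms = np.where(margin > 0, margin * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(terms.sum())


def _entropy_term(counts: np.ndarray) -> float:
    """sum c * log(c / N) over positive cells (the saturated multinomial value)."""
    tot = counts.sum()
    if tot == 0:
        return 0.0
    pos = counts[counts > 0].astype(float)
    return float(np.sum(pos * np.log(pos / tot)))


def _fit_analytic(model: str, tables: TwoLocusTables) -> ModelFit:
    n, m = np.asarray(tables.n, float), np.asarray(tables.m, float)
    mA, mB = m.sum(axis=1), m.sum(axis=0)
    nA, nB = n.sum(axis=1), n.sum(axis=0)
    if model == "M0":
        # f constant cancels: both tables are iid draws from g(pA, pB)
        pA = _freq_from_margin(nA + mA)
        pB = _freq_from_margin(nB + mB)
        ll = (_hwe_margin_loglik(nA + mA, pA) + _hwe_margin_loglik(nB + mB, pB))
        return ModelFit("M0", (pA, pB), np.full((3, 3), 0.5), ll)
    pA = _freq_from_margin(mA)
    pB = _freq_from_margin(mB)
    ctrl = _hwe_margin_loglik(mA, pA) + _hwe_margin_loglik(mB, pB)
    g = np.outer(hwe_probs(pA), hwe_probs(pB))
    N = n.sum()
    if model == "MG":
        # free f lets the case distribution saturate at n/N
        ll = _entropy_term(n) + ctrl
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(g > 0, (n / max(N, 1)) / g, 0.0)
        fmax = f.max()
        f = np.clip(f / fmax * 0.5 if fmax > 0 else f + 0.5, PEN_LO, PEN_HI)
        return ModelFit("MG", (pA, pB), f, ll)
    if model == "MM":
        # f = a_i b_j makes the case distribution an arbitrary product measure,
        # so the case term maximizes at the independence fit of the n margins
        ll = _entropy_term(nA) + _entropy_term(nB) + ctrl
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(hwe_probs(pA) > 0, (nA / max(N, 1)) / hwe_probs(pA), 0.0)
            b = np.where(hwe_probs(pB) > 0, (nB / max(N, 1)) / hwe_probs(pB), 0.0)
        scale = max(a.max(), 1e-12) * max(b.max(), 1e-12)
        f = np.clip(np.outer(a, b) / scale * 0.5, PEN_LO, PEN_HI)
        return ModelFit("MM", (pA, pB), f, ll)
    raise ValueError(f"no analytic fit for model {model!r}")


# ---------------------------------------------------------------------------
# Numeric fitting

def _pack_bounds(model: str) -> list[tuple[float, float]]:
    fb = [(FREQ_LO, FREQ_HI)] * 2
    if model == "M0":
        return fb + [(PEN_LO, PEN_HI)]
    if model in ("MM", "MR"):
        return fb + [(PEN_LO, PEN_HI)] * 6
    return fb + [(PEN_LO, PEN_HI)] * 9


def _unpack(model: str, x: np.ndarray):
    return float(x[0]), float(x[1]), penetrance_matrix(model, x[2:])


def _fit_numeric(model: str, tables: TwoLocusTables, n_restarts: int = 10,
                 seed: int = 0) -> ModelFit:
    rng = np.random.default_rng(seed)
    bounds = _pack_bounds(model)

    def neg(x):
        pA, pB, f = _unpack(model, x)
        ll = loglik(pA, pB, f, tables)
        return -ll if np.isfinite(ll) else 1e12

    m = np.asarray(tables.m, float)
    moment = np.concatenate([
        [_freq_from_margin(m.sum(axis=1)), _freq_from_margin(m.sum(axis=0))],
        np.full(len(bounds) - 2, 0.1),
    ])
    starts = [moment]
    for _ in range(n_restarts):
        starts.append(np.concatenate([
            rng.uniform(0.05, 0.95, size=2),
            rng.uniform(0.01, 0.99, size=len(bounds) - 2),
        ]))
    best = None
    used = 0
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        used += 1
        if res.fun < 1e11 and (best is None or res.fun < best.fun - 1e-9):
            best = res
    if best is None:
        return ModelFit(model, (np.nan, np.nan), np.full((3, 3), np.nan),
                        -np.inf, converged=False, n_restarts_used=used)
    pA, pB, f = _unpack(model, best.x)
    return ModelFit(model, (pA, pB), f, -float(best.fun), converged=True,
                    n_restarts_used=used)


def fit_model(model: str, tables: TwoLocusTables, method: str = "auto",
              n_restarts: int = 10, seed: int = 0) -> ModelFit:
    """Maximum-likelihood fit of one penetrance model to a table pair.

    ``method="auto"`` uses the exact analytic maximizer for M0, MM and MG
    and the seeded multi-restart numeric optimizer for MR; ``"numeric"``
    forces the optimizer for any model (useful for cross-checks).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if method == "auto":
        if model == "MR":
            return _fit_numeric(model, tables, n_restarts=n_restarts, seed=seed)
        return _fit_analytic(model, tables)
    if method == "analytic":
        return _fit_analytic(model, tables)
    if method == "numeric":
        return _fit_numeric(model, tables, n_restarts=n_restarts, seed=seed)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Likelihood-ratio tests and classification

def lrt(fit_small: ModelFit, fit_large: ModelFit, df: int | None = None) -> float:
    """Chi-square p-value for a nested likelihood-ratio comparison.

    The statistic 2*(l_large - l_small) is clipped at zero (optimizer noise
    can leave a nested fit marginally above its parent).  ``df`` defaults to
    the difference in identifiable parameter counts.
    """
    if not (fit_small.converged and fit_large.converged):
        return float("nan")
    if df is None:
        df = N_PARAMS[fit_large.model] - N_PARAMS[fit_small.model]
    lam = max(0.0, 2.0 * (fit_large.loglik - fit_small.loglik))
    return float(stats.chi2.sf(lam, df=df))


def classify_pair(p_02: float, p_12: float, p_m2: float,
                  p02_threshold: float = 1.0e-4,
                  pm2_threshold: float = 0.05,
                  p12_epistasis: float = 1.0e-4,
                  p12_heterogeneity: float = 0.05) -> str:
    """Label a pair from its three LRT p-values.

    "not-reported" unless P_02 clears the reporting threshold; reported
    pairs whose general-model fit does not beat the multiplicative model
    (P_M2 >= 0.05) are "multiplicative-consistent"; otherwise small P_12
    means epistasis, large P_12 heterogeneity, and the band in between is
    reported but left unlabeled.
    """
    if np.isnan(p_02):
        return "not-reported"
    if p_02 >= p02_threshold:
        return "not-reported"
    if not (p_m2 < pm2_threshold):
        return "multiplicative-consistent"
    if p_12 < p12_epistasis:
        return "epistasis"
    if p_12 > p12_heterogeneity:
        return "heterogeneity"
    return "reported-unlabeled"


def expected_null_pairs(n_pairs: int, alpha: float) -> int:
    """Expected count of pairs crossing a secondary threshold by chance."""
    return int(round(n_pairs * alpha))


def evaluate_pair(tables: TwoLocusTables, n_restarts: int = 10, seed: int = 0,
              **thresholds) -> tuple[float, float, float, str]:
    """Fit all four models to one table pair and classify it."""
    fits = {mdl: fit_model(mdl, tables, n_restarts=n_restarts, seed=seed)
            for mdl in MODELS}
    p_02 = lrt(fits["M0"], fits["MG"])
    p_12 = lrt(fits["MR"], fits["MG"])
    p_m2 = lrt(fits["MM"], fits["MG"])
    label = classify_pair(p_02, p_12, p_m2, **thresholds)
    return p_02, p_12, p_m2, label


# ---------------------------------------------------------------------------
# Pair enumeration and panel driver

def cross_region_pairs(snps: list[str], region_of: dict) -> list[tuple[str, str]]:
    """All SNP pairs whose members lie in different regions.

    Within-region pairs are excluded as confounded by linkage
    disequilibrium.  SNPs missing from ``region_of`` are ignored.
    """
    usable = [s for s in snps if s in region_of]
    return [(a, b) for a, b in itertools.combinations(usable, 2)
            if region_of[a] != region_of[b]]


def analyze_pairs(data, pairs: list[tuple[str, str]], min_families: int = 20,
                  n_restarts: int = 10, seed: int = 0,
                  **thresholds) -> pd.DataFrame:
    """Run the four-model interaction test over a list of marker pairs.

    ``data`` is a hard-called :class:`~triogwas.trio_data.FamilyData`.  One
    affected offspring per family is used (the first in pedigree order).
    Pairs with fewer than ``min_families`` complete families are skipped
    with a warning.  Returns one row per tested pair.
    """
    idx = {s: i for i, s in enumerate(data.markers["id"])}
    trios = data.trios[data.trios["affected"]].groupby("fid", sort=False).head(1)
    sel = trios.index.to_numpy()
    F, M, C = data.trio_genotypes()
    F, M, C = F[sel], M[sel], C[sel]
    rows = []
    for snp_a, snp_b in pairs:
        ia, ib = idx[snp_a], idx[snp_b]
        tables = tabulate_two_locus(F[:, ia], M[:, ia], C[:, ia],
                                    F[:, ib], M[:, ib], C[:, ib])
        if tables.n_families < min_families:
            logger.warning("pair (%s, %s): only %d complete families (< %d); skipped",
                           snp_a, snp_b, tables.n_families, min_families)
            continue
        p_02, p_12, p_m2, label = evaluate_pair(tables, n_restarts=n_restarts,
                                            seed=seed, **thresholds)
        rows.append(InteractionResult(snp_a, snp_b, tables.n_families,
                                      p_02, p_12, p_m2, label))
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["snp_a", "snp_b", "n_families",
                                 "p_02", "p_12", "p_m2", "classification"])
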