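"""Transmission disequilibrium tests for trio data.

Three flavours are provided:

* the classical TDT on hard genotype calls: each heterozygous parent
  contributes one transmission of A1 (``T``) or of A2 (``U``) and the
  statistic is ``(T - U)^2 / (T + U)`` on a chi-square with 1 df;
* the expected-count TDT for imputed data: the transmission counts are
  replaced by their expectations over the genotype posterior probabilities
  of the three trio members, averaging over all 27 joint hard-genotype
  configurations with Mendelian-inconsistent configurations excluded; the
  same chi-square functional is applied to the expected counts;
* the HLA-stratified TDT: trios are split into "high" and "low" risk groups
  by the affected offspring's HLA-DQ genotype, each group is tested
  separately, and markers are ranked by the pooled weighted chi-square
  ``sum_g (T_g - U_g)^2 / sum_g (T_g + U_g)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trio_data import MISSING, FamilyData, mendelian_consistent

__all__ = [
    "TransmissionCounts", "TdtResult", "StratifiedResult",
    "count_transmissions", "tdt_test", "expected_transmissions",
    "exp_tdt_test", "stratified_tdt", "weighted_chisq", "assign_stratum",
    "transmission_scan", "expected_transmission_scan", "tdt_scan",
]


@dataclass(frozen=True)
class TransmissionCounts:
    """Counts of parental transmissions of allele A1 (t) and A2 (u)."""

    t: float
    u: float

    def __post_init__(self) -> None:
        if self.t < 0 or self.u < 0:
            raise ValueError("transmission counts must be non-negative")

    def __add__(self, other: "TransmissionCounts") -> "TransmissionCounts":
        return TransmissionCounts(self.t + other.t, self.u + other.u)

    @property
    def informative(self) -> bool:
        return self.t + self.u > 0


@dataclass(frozen=True)
class TdtResult:
    counts: TransmissionCounts
    chisq: float
    p: float          # NaN when the marker is non-informative
    odds: float       # t/u transmission odds; NaN when u == 0


@dataclass(frozen=True)
class StratifiedResult:
    per_stratum: dict
    weighted_chisq: float


# ---------------------------------------------------------------------------
# Hard-call counting

def count_transmissions(father: int, mother: int, child: int) -> TransmissionCounts:
    """Classical TDT counting for one fully typed, consistent trio.

    Only heterozygous parents are informative.  With ``h`` A1 alleles forced
    by homozygous-A1 parents and ``k`` heterozygous parents, the child's A1
    dosage determines how many of the ``k`` free transmissions were A1.
    """
    if min(father, mother, child) < 0:
        raise ValueError("count_transmissions requires fully typed trios")
    if not mendelian_consistent(father, mother, child):
        raise ValueError("Mendelian-inconsistent trio; mask upstream")
    forced = (father == 2) + (mother == 2)
    hets = (father == 1) + (mother == 1)
    t = child - forced
    return TransmissionCounts(float(t), float(hets - t))


def transmission_scan(F: np.ndarray, M: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate hard-call transmission counts per marker.

    ``F, M, C`` are (n_trios, n_markers) genotype-code matrices.  Trios with
    any missing member or a Mendelian inconsistency at a marker contribute
    nothing there.  Returns per-marker ``(T, U)`` arrays.
    """
    typed = (F >= 0) & (M >= 0) & (C >= 0)
    ok = typed & mendelian_consistent(F, M, C)
    forced = (F == 2).astype(np.int64) + (M == 2).astype(np.int64)
    hets = (F == 1).astype(np.int64) + (M == 1).astype(np.int64)
    t = np.where(ok, C - forced, 0)
    u = np.where(ok, hets - (C - forced), 0)
    return t.sum(axis=0).astype(float), u.sum(axis=0).astype(float)


# ---------------------------------------------------------------------------
# Chi-square test

def tdt_test(counts: TransmissionCounts) -> TdtResult:
    """1-df chi-square TDT on (possibly real-valued) transmission counts."""
    t, u = counts.t, counts.u
    if t + u <= 0:
        return TdtResult(counts, 0.0, float("nan"), float("nan"))
    chisq = (t - u) ** 2 / (t + u)
    p = float(stats.chi2.sf(chisq, df=1))
    odds = t / u if u > 0 else float("nan")
    return TdtResult(counts, float(chisq), p, odds)


#: The expected-count TDT applies the same functional to expected counts.
exp_tdt_test = tdt_test


# ---------------------------------------------------------------------------
# Expected-count transmissions from posteriors

def _configurations():
    g = np.arange(3)
    f, m, c = np.meshgrid(g, g, g, indexing="ij")
    f, m, c = f.ravel(), m.ravel(), c.ravel()
    cons = mendelian_consistent(f, m, c)
    forced = (f == 2).astype(int) + (m == 2).astype(int)
    hets = (f == 1).astype(int) + (m == 1).astype(int)
    t = np.where(cons, c - forced, 0)
    u = np.where(cons, hets - (c - forced), 0)
    return f, m, c, cons.astype(float), t.astype(float), u.astype(float)


_CF, _CM, _CC, _CONS, _CT, _CU = _configurations()


def expected_transmissions(father, mother, child, min_mass: float = 1e-9) -> TransmissionCounts:
    """Expected transmission counts for one trio of posterior triplets.

    The 27 joint hard-genotype configurations are weighted by the product of
    the member posteriors; Mendelian-inconsistent configurations get weight
    zero and the rest are renormalized, so a fully certain trio reduces
    exactly to :func:`count_transmissions`.

    Raises ``ValueError`` when the Mendelian-consistent probability mass is
    below ``min_mass`` (the trio carries no usable information).
    """
    pf = np.asarray(father, dtype=float)
    pm = np.asarray(mother, dtype=float)
    pc = np.asarray(child, dtype=float)
    w = pf[_CF] * pm[_CM] * pc[_CC]
    mass = float(w @ _CONS)
    if mass < min_mass:
        raise ValueError("trio has (near-)zero Mendelian-consistent posterior mass")
    return TransmissionCounts(float(w @ _CT) / mass, float(w @ _CU) / mass)


def expected_transmission_scan(PF: np.ndarray, PM: np.ndarray, PC: np.ndarray,
                               min_mass: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate expected transmission counts per marker.

    ``PF, PM, PC`` are (n_trios, n_markers, 3) posterior arrays.  Trios whose
    consistent mass falls below ``min_mass`` at a marker are skipped there.
    """
    w = PF[:, :, _CF] * PM[:, :, _CM] * PC[:, :, _CC]
    mass = w @ _CONS
    usable = mass > min_mass
    denom = np.where(usable, mass, 1.0)
    t = np.where(usable, (w @ _CT) / denom, 0.0)
    u = np.where(usable, (w @ _CU) / denom, 0.0)
    return t.sum(axis=0), u.sum(axis=0)


# ---------------------------------------------------------------------------
# Stratified TDT

def assign_stratum(dqa_risk_carrier: bool, dqb1_02_copies: int) -> str:
    """HLA-DQ risk stratum of an affected offspring.

    "high" iff the child carries the DQA1*02/05 risk allele AND is homozygous
    for DQB1*02 (two copies); everyone else is "low".
    """
    if dqb1_02_copies not in (0, 1, 2):
        raise ValueError("DQB1*02 copy number must be 0, 1 or 2")
    return "high" if (dqa_risk_carrier and dqb1_02_copies == 2) else "low"


def weighted_chisq(counts_by_stratum) -> float:
    """Pooled ranking statistic ``sum_g (T_g-U_g)^2 / sum_g (T_g+U_g)``.

    Strata with no informative transmissions contribute (0, 0) to both sums.
    """
    num = 0.0
    den = 0.0
    for c in counts_by_stratum:
        num += (c.t - c.u) ** 2
        den += c.t + c.u
    return num / den if den > 0 else 0.0


def stratified_tdt(counts_by_stratum: dict) -> StratifiedResult:
    """Per-stratum TDT plus the weighted chi-square ranking statistic.

    ``counts_by_stratum`` maps stratum label -> TransmissionCounts.  With a
    single stratum the weighted chi-square equals that stratum's chi-square.
    """
    per = {name: tdt_test(c) for name, c in counts_by_stratum.items()}
    return StratifiedResult(per, weighted_chisq(counts_by_stratum.values()))


# ---------------------------------------------------------------------------
# Panel-level scan

def tdt_scan(data: FamilyData, mode: str = "hard",
             affected_only: bool = True,
             one_per_family: bool = False,
             min_mass: float = 1e-9) -> pd.DataFrame:
    """Per-marker TDT over a panel.

    Parameters
    ----------
    mode : {"hard", "expected"}
        Hard-call counting or expected counts from posteriors.
    affected_only : bool
        Restrict to trios with an affected offspring (the TDT's premise).
    one_per_family : bool
        Keep only the first affected offspring of each family (by pedigree
        order) instead of treating affected siblings as separate trios.

    Returns a frame with columns Chr, SNP, BP, A1, A2, T, U, chisq, p, odds.
    """
    trios = data.trios
    if affected_only:
        trios = trios[trios["affected"]]
    if one_per_family:
        trios = trios.groupby("fid", sort=False).head(1)
    sel = trios.index.to_numpy()
    if mode == "hard":
        F, M, C = data.trio_genotypes()
        T, U = transmission_scan(F[sel], M[sel], C[sel])
    elif mode == "expected":
        PF, PM, PC = data.trio_posteriors()
        T, U = expected_transmission_scan(PF[sel], PM[sel], PC[sel], min_mass=min_mass)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _results_frame(data.markers, T, U)


def stratified_scan(data: FamilyData, strata=("high", "low"),
                    one_per_family: bool = False) -> pd.DataFrame:
    """Per-marker stratified TDT from hard calls.

    The trio table must carry a ``stratum`` column; trios with a missing
    stratum are excluded.  Returns one row per marker with per-stratum
    T/U/chisq/p columns and the weighted chi-square, sorted by it.
    """
    if "stratum" not in data.trios.columns:
        raise ValueError("trio table has no 'stratum' column")
    trios = data.trios[data.trios["affected"] & data.trios["stratum"].isin(strata)]
    if one_per_family:
        trios = trios.groupby("fid", sort=False).head(1)
    F, M, C = data.trio_genotypes()
    out = data.markers.copy()
    per = {}
    for s in strata:
        sel = trios.index[trios["stratum"] == s].to_numpy()
        T, U = transmission_scan(F[sel], M[sel], C[sel])
        per[s] = (T, U)
        chisq, p = _vector_chisq(T, U)
        out[f"T_{s}"] = T
        out[f"U_{s}"] = U
        out[f"chisq_{s}"] = chisq
        out[f"p_{s}"] = p
    num = sum((T - U) ** 2 for T, U in per.values())
    den = sum(T + U for T, U in per.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        out["weighted_chisq"] = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return out.sort_values("weighted_chisq", ascending=False).reset_index(drop=True)


def _vector_chisq(T: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    informative = (T + U) > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = np.where(informative, (T - U) ** 2 / np.maximum(T + U, 1e-300), 0.0)
    p = np.where(informative, stats.chi2.sf(chisq, df=1), np.nan)
    return chisq, p


def _results_frame(markers: pd.DataFrame, T: np.ndarray, U: np.ndarray) -> pd.DataFrame:
    chisq, p = _vector_chisq(T, U)
    with np.errstate(invalid="ignore", divide="ignore"):
        odds = np.where(U > 0, T / np.maximum(U, 1e-300), np.nan)
    return pd.DataFrame({
        "Chr": markers["chrom"].to_numpy(),
        "SNP": markers["id"].to_numpy(),
        "BP": markers["bp"].to_numpy(),
        "A1": markers["a1"].to_numpy(),
        "A2": markers["a2"].to_numpy(),
        "T": T, "U": U, "chisq": chisq, "p": p, "odds": odds,
    })
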