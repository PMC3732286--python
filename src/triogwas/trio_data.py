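"""Reading, validation and QC of trio genotype data.

Genotypes are encoded throughout the package as the number of copies of the
A1 allele an individual carries: ``2`` (A1/A1, "AA"), ``1`` (A1/A2, "AB"),
``0`` (A2/A2, "BB") and ``-1`` for missing.  Imputation posteriors are stored
as arrays whose last axis is indexed the same way, so ``post[..., k]`` is the
posterior probability of carrying ``k`` copies of A1.

Two text formats are read: whitespace-delimited PLINK FAM/PED pedigrees
(first six columns: family, individual, father, mother, sex, phenotype; an
affected individual has phenotype code 2) and Oxford GEN/SAMPLE genotype
probability files (one marker per row: chromosome, marker id, position,
allele A1, allele A2, then three probabilities P(AA), P(AB), P(BB) per
sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
#: Readable aliases for the integer genotype codes (copies of A1).
BB, AB, AA = 0, 1, 2

_STATE_NAMES = {AA: "AA", AB: "AB", BB: "BB", MISSING: "MISSING"}


class PedigreeParseError(ValueError):
    """A pedigree line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class Marker:
    """A biallelic marker: name, chromosome, 1-based position and alleles."""

    id: str
    chrom: str
    bp: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.bp <= 0:
            raise ValueError(f"marker {self.id}: bp must be positive")
        if self.a1 == self.a2:
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass
class FamilyData:
    """Container for a family genotype panel.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per individual: ``fid, iid, father, mother, sex, affected``.
    trios : pandas.DataFrame
        One row per offspring with both parents present: integer row indices
        ``father_idx, mother_idx, child_idx`` into ``samples`` plus ``fid``,
        ``iid`` (offspring id), ``affected`` and an optional ``stratum``
        column ({"high", "low"}) for the HLA-stratified analysis.
    markers : pandas.DataFrame
        One row per marker: ``id, chrom, bp, a1, a2``.
    posteriors : numpy.ndarray or None
        Shape ``(n_samples, n_markers, 3)``; last axis indexed by A1 copies.
    genotypes : numpy.ndarray or None
        Hard calls, shape ``(n_samples, n_markers)``, int8.
    """

    samples: pd.DataFrame
    trios: pd.DataFrame
    markers: pd.DataFrame
    posteriors: np.ndarray | None = None
    genotypes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def founder_mask(self) -> np.ndarray:
        """Boolean mask over samples marking founders (no parent in panel)."""
        return (self.samples["father"].isin(["0", ""]) & self.samples["mother"].isin(["0", ""])).to_numpy()

    def trio_genotypes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Father/mother/child hard-call matrices, each (n_trios, n_markers)."""
        if self.genotypes is None:
            raise ValueError("no hard-called genotypes present; run hard_call_panel first")
        g = self.genotypes
        t = self.trios
        return (g[t["father_idx"].to_numpy()],
                g[t["mother_idx"].to_numpy()],
                g[t["child_idx"].to_numpy()])

    def trio_posteriors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Father/mother/child posterior arrays, each (n_trios, n_markers, 3)."""
        if self.posteriors is None:
            raise ValueError("no posteriors present")
        p = self.posteriors
        t = self.trios
        return (p[t["father_idx"].to_numpy()],
                p[t["mother_idx"].to_numpy()],
                p[t["child_idx"].to_numpy()])


# ---------------------------------------------------------------------------
# Pedigree reading


def read_pedigree(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a whitespace-delimited FAM/PED file.

    Returns ``(samples, trios)`` as described in :class:`FamilyData`.  Only
    the first six columns are used; any trailing genotype columns of a PED
    file are ignored.  An offspring whose father or mother id is ``0`` (or
    absent from the file) is excluded from the trio table with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeParseError(
                    f"{path}: line {lineno}: expected >=6 whitespace-delimited "
                    f"columns, got {len(fields)}")
            fid, iid, father, mother, sex, pheno = fields[:6]
            rows.append((fid, iid, father, mother, sex, pheno))
    samples = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"])
    samples["affected"] = samples["phenotype"] == "2"
    return samples, build_trios(samples)


def build_trios(samples: pd.DataFrame) -> pd.DataFrame:
    """Assemble one trio per offspring whose two parents are in the panel."""
    index = {(f, i): row for row, (f, i) in enumerate(zip(samples["fid"], samples["iid"]))}
    recs = []
    for row, s in samples.iterrows():
        father_missing = s["father"] in ("0", "")
        mother_missing = s["mother"] in ("0", "")
        if father_missing and mother_missing:
            continue  # founder
        if father_missing or mother_missing:
            logger.warning("offspring %s/%s: one parent id missing; trio excluded",
                           s["fid"], s["iid"])
            continue
        fa = index.get((s["fid"], s["father"]))
        mo = index.get((s["fid"], s["mother"]))
        if fa is None or mo is None:
            logger.warning("offspring %s/%s: parent missing from pedigree; trio excluded",
                           s["fid"], s["iid"])
            continue
        if len({fa, mo, row}) != 3:
            logger.warning("offspring %s/%s: degenerate trio (member ids not distinct); excluded",
                           s["fid"], s["iid"])
            continue
        recs.append((s["fid"], s["iid"], fa, mo, row, bool(s["affected"])))
    return pd.DataFrame(recs, columns=["fid", "iid", "father_idx", "mother_idx",
                                       "child_idx", "affected"])


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE reading and writing


def read_sample(path) -> pd.DataFrame:
    """Read an Oxford SAMPLE file (two header lines, then ID_1 ID_2 ...)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df = df.iloc[1:].reset_index(drop=True)  # drop the type-code line
    df = df.rename(columns={"ID_1": "fid", "ID_2": "iid"})
    return df[["fid", "iid"]]


def read_gen(path, n_samples: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Read an Oxford GEN file.

    Row layout: ``chrom id bp a1 a2  p(AA) p(AB) p(BB) ...`` with one
    probability triplet per sample.  Returns the marker table and a
    posterior array of shape ``(n_samples, n_markers, 3)`` indexed by copies
    of A1 on its last axis (note the reversal relative to the file order).
    """
    raw = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str, 1: str, 3: str, 4: str})
    expected = 5 + 3 * n_samples
    if raw.shape[1] != expected:
        raise ValueError(f"{path}: expected {expected} columns for {n_samples} samples, "
                         f"got {raw.shape[1]}")
    markers = raw.iloc[:, :5].copy()
    markers.columns = ["chrom", "id", "bp", "a1", "a2"]
    markers["bp"] = markers["bp"].astype(int)
    probs = raw.iloc[:, 5:].to_numpy(dtype=float).reshape(len(raw), n_samples, 3)
    # file order is (AA, AB, BB); internal order is copies of A1 = (0, 1, 2)
    post = probs[:, :, ::-1].transpose(1, 0, 2).copy()
    return markers.reset_index(drop=True), post


def write_gen(path, markers: pd.DataFrame, posteriors: np.ndarray) -> None:
    """Write an Oxford GEN file (inverse of :func:`read_gen`)."""
    n_samples, n_markers, _ = posteriors.shape
    file_order = posteriors[:, :, ::-1].transpose(1, 0, 2).reshape(n_markers, 3 * n_samples)
    with open(path, "w") as fh:
        for i, m in markers.iterrows():
            probs = " ".join(f"{x:.6g}" for x in file_order[i])
            fh.write(f"{m['chrom']} {m['id']} {m['bp']} {m['a1']} {m['a2']} {probs}\n")


def write_sample(path, samples: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for _, s in samples.iterrows():
            fh.write(f"{s['fid']} {s['iid']} 0\n")


# ---------------------------------------------------------------------------
# Hard calling


def hard_call(posterior, threshold: float = 0.95):
    """Call the genotype whose posterior strictly exceeds ``threshold``.

    ``posterior`` is indexed by copies of A1; the call is returned on the
    same scale, ``MISSING`` when no probability exceeds the threshold.
    Accepts a single triplet or an array whose last axis has length 3.
    """
    p = np.asarray(posterior, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("posterior last axis must have length 3")
    best = np.argmax(p, axis=-1)
    called = np.take_along_axis(p, best[..., None], axis=-1)[..., 0] > threshold
    out = np.where(called, best, MISSING).astype(np.int8)
    return out if out.ndim else int(out)


def hard_call_panel(data: FamilyData, threshold: float = 0.95) -> FamilyData:
    """Hard-call the whole posterior panel in place; returns ``data``."""
    if data.posteriors is None:
        raise ValueError("panel has no posteriors")
    data.genotypes = hard_call(data.posteriors, threshold)
    return data


# ---------------------------------------------------------------------------
# Mendelian consistency


def mendelian_consistent(father, mother, child):
    """Vectorized Mendelian consistency for genotype codes.

    A trio is consistent iff the child's A1 count can be written as the sum
    of one transmitted allele from each parent.  Any MISSING member makes the
    trio vacuously consistent (only fully typed trios are checked).
    """
    f = np.asarray(father)
    m = np.asarray(mother)
    c = np.asarray(child)
    typed = (f >= 0) & (m >= 0) & (c >= 0)
    forced = (f == 2).astype(np.int8) + (m == 2).astype(np.int8)
    hets = (f == 1).astype(np.int8) + (m == 1).astype(np.int8)
    r = c - forced
    ok = (r >= 0) & (r <= hets)
    return np.where(typed, ok, True)


def mendelian_mask(father: int, mother: int, child: int) -> tuple[int, int, int]:
    """Mask a single trio at a single marker, all-or-none."""
    if mendelian_consistent(father, mother, child):
        return father, mother, child
    return MISSING, MISSING, MISSING


def mask_mendelian_panel(data: FamilyData) -> np.ndarray:
    """Family-wise Mendelian masking of the hard-call matrix, in place.

    If any trio in a family is inconsistent at a marker, the genotypes of
    every member of that family are set to MISSING at that marker (mirrors
    masking "for all subjects" within the family).  Returns the boolean
    (n_families_affected) inconsistency matrix per trio for reporting.
    """
    if data.genotypes is None:
        raise ValueError("panel has no hard calls")
    F, M, C = data.trio_genotypes()
    incons = ~mendelian_consistent(F, M, C)  # (n_trios, n_markers)
    fam_of_sample = data.samples["fid"]
    for fid, tgroup in data.trios.groupby("fid"):
        fam_bad = incons[tgroup.index.to_numpy()].any(axis=0)
        if fam_bad.any():
            member_rows = np.flatnonzero((fam_of_sample == fid).to_numpy())
            data.genotypes[np.ix_(member_rows, np.flatnonzero(fam_bad))] = MISSING
    return incons


# ---------------------------------------------------------------------------
# Marker QC


def marker_qc(data: FamilyData, call_rate_threshold: float = 0.97,
              maf_report_threshold: float = 0.01,
              apply_maf_filter: bool = False) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-marker QC on the hard-call matrix.

    Markers with call rate <= ``call_rate_threshold`` are dropped (the call
    rate must be strictly above the threshold to survive, denominator = all
    samples in the assembled panel).  MAF is computed from founders and
    reported against ``maf_report_threshold``; the MAF filter is applied only
    when ``apply_maf_filter`` is set.

    Returns ``(keep_mask, report)`` where ``report`` has one row per marker.
    """
    if data.genotypes is None:
        raise ValueError("panel has no hard calls")
    if data.n_markers == 0:
        raise ValueError("empty marker panel")
    g = data.genotypes
    called = g >= 0
    call_rate = called.mean(axis=0)
    founders = data.founder_mask()
    fg = g[founders]
    fcalled = fg >= 0
    n_alleles = 2 * fcalled.sum(axis=0)
    a1_count = np.where(fcalled, fg, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a1_freq = np.where(n_alleles > 0, a1_count / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(a1_freq, 1.0 - a1_freq)
    keep = call_rate > call_rate_threshold
    maf_pass = maf >= maf_report_threshold
    if apply_maf_filter:
        keep = keep & np.nan_to_num(maf_pass, nan=False)
    report = data.markers.copy()
    report["call_rate"] = call_rate
    report["maf"] = maf
    report["pass_call_rate"] = call_rate > call_rate_threshold
    report["pass_maf"] = maf_pass
    report["kept"] = keep
    return keep, report


def subset_markers(data: FamilyData, keep: np.ndarray) -> FamilyData:
    """Return a new FamilyData restricted to the markers in ``keep``."""
    keep = np.asarray(keep)
    if keep.dtype == bool:
        idx = np.flatnonzero(keep)
    else:
        idx = keep
    return FamilyData(
        samples=data.samples,
        trios=data.trios,
        markers=data.markers.iloc[idx].reset_index(drop=True),
        posteriors=None if data.posteriors is None else data.posteriors[:, idx],
        genotypes=None if data.genotypes is None else data.genotypes[:, idx],
    )


def genotype_name(code: int) -> str:
    """Human-readable name ("AA"/"AB"/"BB"/"MISSING") for a genotype code."""
    return _STATE_NAMES[int(code)]
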