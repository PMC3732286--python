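"""Multi-criteria marker selection, region merging and gene annotation.

Markers enter the downstream pathway/interaction analyses if they satisfy at
least one of three inclusion criteria (all comparisons strict):

1. significance: association p-value < 3.0e-4;
2. replication: p < 0.01 internally and p < 0.05 in an external study, with
   p_int * p_ext < 5.0e-5 and the same allelic direction in both;
3. effect size: transmission ratio T/U < 0.2 or > 5 together with p < 2.0e-3.

Selected markers are merged into regions: a region is a maximal run of
selected markers on one chromosome in which adjacent markers are separated
by less than 100 kb.  The extended HLA interval (chr6:27-34 Mb) can be
excluded, and markers are annotated with the five closest genes within
250 kb (falling back to the single nearest gene when none is that close).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HLA_CHROM = "6"
HLA_START = 27_000_000
HLA_END = 34_000_000


@dataclass(frozen=True)
class SelectionThresholds:
    """Criterion thresholds; defaults are the published analysis settings."""

    p_significance: float = 3.0e-4
    p_internal: float = 0.01
    p_external: float = 0.05
    p_product: float = 5.0e-5
    ratio_low: float = 0.2
    ratio_high: float = 5.0
    p_effect: float = 2.0e-3
    region_gap: int = 100_000


def criterion_significance(p: float, thresholds: SelectionThresholds = SelectionThresholds()) -> bool:
    """Criterion 1: p strictly below the significance cut-off."""
    return bool(p is not None and not np.isnan(p) and p < thresholds.p_significance)


def criterion_replication(p_int: float, p_ext: float, dir_int: int, dir_ext: int,
                          thresholds: SelectionThresholds = SelectionThresholds()) -> bool:
    """Criterion 2: nominal internal + external support, small product, same direction.

    Directions are +1/-1 for risk/protective on a shared reference allele;
    harmonize before calling (see :func:`harmonized_external_direction`).
    """
    for v in (p_int, p_ext):
        if v is None or np.isnan(v):
            return False
    return bool(p_int < thresholds.p_internal and p_ext < thresholds.p_external
                and p_int * p_ext < thresholds.p_product and dir_int == dir_ext)


def criterion_effect_size(t: float, u: float, p: float,
                          thresholds: SelectionThresholds = SelectionThresholds()) -> bool:
    """Criterion 3: extreme transmission ratio with nominal significance."""
    if p is None or np.isnan(p):
        return False
    if t + u <= 0:
        return False
    ratio = t / u if u > 0 else float("inf")
    return bool((ratio < thresholds.ratio_low or ratio > thresholds.ratio_high)
                and p < thresholds.p_effect)


def harmonized_external_direction(a1: str, a2: str, ext_a1: str, ext_or: float):
    """Direction (+1/-1) of an external odds ratio on the internal A1 allele.

    Returns None (with a warning upstream) if the external effect allele
    matches neither internal allele.
    """
    if ext_a1 == a1:
        return 1 if ext_or > 1 else -1
    if ext_a1 == a2:
        return 1 if ext_or < 1 else -1
    return None


def select_markers(results: pd.DataFrame, external: pd.DataFrame | None = None,
                   thresholds: SelectionThresholds = SelectionThresholds()) -> pd.DataFrame:
    """Evaluate the three criteria over a TDT results frame.

    ``results`` must have columns SNP, Chr, BP, A1, A2, T, U, p, odds;
    ``external`` (optional) columns SNP, A1, OR, p.  Returns the results
    frame with boolean columns crit_significance / crit_replication /
    crit_effect_size and ``selected`` (their union).
    """
    out = results.copy()
    out["crit_significance"] = [criterion_significance(p, thresholds) for p in out["p"]]

    crit2 = np.zeros(len(out), dtype=bool)
    if external is not None and len(external):
        ext = external.set_index("SNP")
        for i, row in enumerate(out.itertuples(index=False)):
            if row.SNP not in ext.index:
                continue
            e = ext.loc[row.SNP]
            dir_ext = harmonized_external_direction(row.A1, row.A2, str(e["A1"]), float(e["OR"]))
            if dir_ext is None:
                logger.warning("marker %s: external alleles do not match; dropped from "
                               "replication criterion", row.SNP)
                continue
            dir_int = 1 if (row.U > 0 and row.T / row.U > 1) or row.U == 0 else -1
            crit2[i] = criterion_replication(row.p, float(e["p"]), dir_int, dir_ext, thresholds)
    out["crit_replication"] = crit2

    out["crit_effect_size"] = [criterion_effect_size(t, u, p, thresholds)
                               for t, u, p in zip(out["T"], out["U"], out["p"])]
    out["selected"] = (out["crit_significance"] | out["crit_replication"]
                       | out["crit_effect_size"])
    return out


def build_regions(markers: pd.DataFrame, gap: int = 100_000) -> pd.DataFrame:
    """Merge bp-sorted markers into regions with inter-marker gaps < ``gap``.

    ``markers`` needs columns SNP (or id), Chr (or chrom) and BP (or bp).
    Returns one row per region: region_id, chrom, start_bp, end_bp, n_markers
    and the member SNP ids (comma-joined, sorted by position).  A gap of
    exactly ``gap`` starts a new region (strict "less than" within a region).
    """
    df = _norm_cols(markers)
    records = []
    rid = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        bps = grp["bp"].to_numpy()
        ids = grp["snp"].to_numpy()
        start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or bps[i] - bps[i - 1] >= gap:
                records.append((rid, chrom, int(bps[start]), int(bps[i - 1]),
                                i - start, ",".join(ids[start:i])))
                rid += 1
                start = i
    return pd.DataFrame(records, columns=["region_id", "chrom", "start_bp", "end_bp",
                                          "n_markers", "members"])


def region_of_marker(regions: pd.DataFrame) -> dict:
    """Map SNP id -> region_id from a :func:`build_regions` frame."""
    out = {}
    for row in regions.itertuples(index=False):
        for snp in row.members.split(","):
            out[snp] = row.region_id
    return out


def exclude_hla(markers: pd.DataFrame, chrom: str = HLA_CHROM,
                start: int = HLA_START, end: int = HLA_END) -> pd.DataFrame:
    """Drop markers inside the extended HLA interval (inclusive bounds)."""
    df = _norm_cols(markers)
    inside = (df["chrom"].astype(str) == str(chrom)) & (df["bp"] >= start) & (df["bp"] <= end)
    return markers.loc[~inside.to_numpy()].reset_index(drop=True)


def annotate_genes(chrom: str, bp: int, genes: pd.DataFrame,
                   max_genes: int = 5, window: int = 250_000) -> list[tuple[str, int]]:
    """Nearest genes for a marker position.

    ``genes`` has 1-based inclusive columns chrom, start, end, name (use
    :func:`read_gene_bed` for BED input).  Returns up to ``max_genes``
    ``(name, distance)`` pairs within ``window`` bp of the marker, closest
    first (distance 0 when the marker lies inside the gene, ties broken by
    name); if none is within the window, the single nearest gene on the
    chromosome; empty list (with a warning) if the chromosome has no genes.
    """
    g = genes[genes["chrom"].astype(str) == str(chrom)]
    if g.empty:
        logger.warning("no genes on chromosome %s; marker at %d left unannotated", chrom, bp)
        return []
    start = g["start"].to_numpy()
    end = g["end"].to_numpy()
    inside = (bp >= start) & (bp <= end)
    dist = np.where(inside, 0, np.minimum(np.abs(bp - start), np.abs(bp - end)))
    order = sorted(range(len(g)), key=lambda i: (dist[i], g["name"].iloc[i]))
    within = [(g["name"].iloc[i], int(dist[i])) for i in order if dist[i] <= window]
    if within:
        return within[:max_genes]
    i = order[0]
    return [(g["name"].iloc[i], int(dist[i]))]


def read_gene_bed(path) -> pd.DataFrame:
    """Read a gene BED file (0-based half-open) into 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str})
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def _norm_cols(df: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower(): c for c in df.columns}
    ren = {}
    for want, aliases in {"chrom": ("chr", "chrom"), "bp": ("bp",), "snp": ("snp", "id")}.items():
        for a in aliases:
            if a in cols:
                ren[want] = cols[a]
                break
        else:
            raise KeyError(f"marker frame needs a {want} column")
    out = pd.DataFrame({k: df[v] for k, v in ren.items()})
    out["bp"] = out["bp"].astype(int)
    return out
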