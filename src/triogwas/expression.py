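"""Relative qPCR quantification (delta-delta Ct) with a multi-gene reference.

Each sample's reference value is the arithmetic mean of its reference-gene
Ct values, which equals the geometric mean of the corresponding 2^-Ct
quantities.  For a target assay, dCt = Ct_target - Ct_reference and the
relative quantity is RQ = 2^-dCt.  Fold changes compare group mean RQs
(cases over controls), reported as a magnitude >= 1 with an UP/DOWN
direction; group differences are tested on the dCt scale (Welch's t-test by
default, Mann-Whitney optionally) and Bonferroni-corrected over the number
of assays tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample", "group", "gene", "assay", "ct")


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    assay: str
    fold_change: float
    direction: str
    p_raw: float
    p_corrected: float


def reference_value(cts) -> float:
    """Per-sample reference Ct: the mean of the reference-gene Cts."""
    cts = np.asarray(cts, dtype=float)
    if cts.size == 0:
        raise ValueError("no reference-gene Ct values for sample")
    return float(cts.mean())


def relative_quantity(target_ct: float, reference_ct: float) -> float:
    """RQ = 2^-(Ct_target - Ct_reference)."""
    return float(2.0 ** -(target_ct - reference_ct))


def fold_change(case_rqs, control_rqs) -> tuple[float, str]:
    """Ratio of group mean RQs, as (magnitude >= 1, direction in cases).

    Equal means report (1.0, "UP") by the tie rule.
    """
    r = float(np.mean(case_rqs) / np.mean(control_rqs))
    return (r, "UP") if r >= 1.0 else (1.0 / r, "DOWN")


def group_test(case_dcts, control_dcts, test: str = "welch") -> float:
    """Two-sided test of a group difference in dCt; NaN if a group has < 2."""
    a = np.asarray(case_dcts, dtype=float)
    b = np.asarray(control_dcts, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, p * m)."""
    if np.isnan(p_raw):
        return float("nan")
    return float(min(1.0, p_raw * m))


def ddct_analysis(ct_table: pd.DataFrame, reference_genes: list[str],
                  test: str = "welch", bonferroni_m: int | None = None) -> pd.DataFrame:
    """Full delta-delta Ct comparison of cases vs controls.

    ``ct_table`` is long-format with columns sample, group ("case"/
    "control"), gene, assay, ct.  Samples without any reference-gene
    measurement are excluded with a warning.  ``bonferroni_m`` defaults to
    the number of assays with a computable p-value.

    Returns one row per non-reference assay: gene, assay, fold_change,
    direction, n_case, n_control, p_raw, p_corrected, sorted by p_raw.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    df = ct_table.copy()
    df["is_reference"] = df["gene"].isin(reference_genes)

    ref = (df[df["is_reference"]].groupby("sample")["ct"].mean()
           .rename("reference_ct"))
    dropped = set(df["sample"]) - set(ref.index)
    for s in sorted(dropped):
        logger.warning("sample %s has no reference-gene Ct; excluded", s)
    df = df[~df["is_reference"]].merge(ref, on="sample")
    df["dct"] = df["ct"] - df["reference_ct"]
    df["rq"] = 2.0 ** -df["dct"]

    rows = []
    for (gene, assay), grp in df.groupby(["gene", "assay"], sort=False):
        case = grp[grp["group"] == "case"]
        ctrl = grp[grp["group"] == "control"]
        if len(case) == 0 or len(ctrl) == 0:
            logger.warning("assay %s/%s: a group is empty; skipped", gene, assay)
            continue
        fc, direction = fold_change(case["rq"], ctrl["rq"])
        p = group_test(case["dct"], ctrl["dct"], test=test)
        rows.append((gene, assay, fc, direction, len(case), len(ctrl), p))
    out = pd.DataFrame(rows, columns=["gene", "assay", "fold_change", "direction",
                                      "n_case", "n_control", "p_raw"])
    m = bonferroni_m if bonferroni_m is not None else int(out["p_raw"].notna().sum())
    out["p_corrected"] = [bonferroni(p, m) for p in out["p_raw"]]
    return out.sort_values("p_raw", na_position="last").reset_index(drop=True)


def normalize_to_controls(rqs: pd.Series, groups: pd.Series) -> pd.Series:
    """Scale RQs so the control-group mean equals 1 (plotting convention)."""
    ctrl_mean = rqs[groups == "control"].mean()
    return rqs / ctrl_mean
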