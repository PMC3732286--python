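"""Stage orchestration: qc -> tdt -> stratify -> select -> interact -> express.

Each stage writes a TSV artifact plus an entry in a JSON run manifest
recording the parameters used, SHA-256 hashes of its inputs and basic
counts, so a rerun on identical inputs is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import ddct_analysis
from .interaction import analyze_pairs, cross_region_pairs
from .selection import (SelectionThresholds, build_regions, exclude_hla,
                        region_of_marker, select_markers)
from .tdt import assign_stratum, stratified_scan, tdt_scan
from .trio_data import (FamilyData, hard_call_panel, marker_qc,
                        mask_mendelian_panel, read_gen, read_pedigree,
                        read_sample, subset_markers)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "hard_call_threshold": 0.95,
    "call_rate_threshold": 0.97,
    "maf_report_threshold": 0.01,
    "apply_maf_filter": False,
    "exclude_hla": True,
    "stratified": False,
    "selection": {},           # overrides for SelectionThresholds fields
    "min_families": 20,
    "n_restarts": 10,
    "one_per_family": False,
    "expression": False,
    "reference_genes": ["ACTB", "EPCAM", "PGK1"],
    "expression_test": "welch",
    "bonferroni_m": None,
    "seed": 0,
}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_inputs(config: dict) -> FamilyData:
    samples, trios = read_pedigree(config["pedigree"])
    sample_order = read_sample(config["sample"])
    if not (sample_order["iid"].to_numpy() == samples["iid"].to_numpy()).all():
        raise ValueError("SAMPLE file order does not match the pedigree")
    markers, post = read_gen(config["gen"], n_samples=len(samples))
    return FamilyData(samples=samples, trios=trios, markers=markers, posteriors=post)


def attach_strata(data: FamilyData, strata_path) -> None:
    """Attach HLA strata from a per-offspring TSV.

    Accepts either a precomputed ``stratum`` column or the raw HLA labels
    ``dqa_carrier`` (0/1) and ``dqb1_copies`` (0/1/2), keyed by fid + iid.
    Offspring without a row are excluded from the stratified analysis.
    """
    tab = pd.read_csv(strata_path, sep="\t", dtype={"fid": str, "iid": str})
    if "stratum" not in tab.columns:
        tab["stratum"] = [assign_stratum(bool(c), int(k))
                          for c, k in zip(tab["dqa_carrier"], tab["dqb1_copies"])]
    key = data.trios[["fid", "iid"]].merge(tab[["fid", "iid", "stratum"]],
                                           on=["fid", "iid"], how="left")
    missing = key["stratum"].isna()
    if missing.any():
        logger.warning("%d offspring lack an HLA stratum label; excluded from "
                       "the stratified analysis", int(missing.sum()))
    data.trios["stratum"] = key["stratum"].to_numpy()


def run_pipeline(config: dict) -> Path:
    """Run all configured stages; returns the artifact directory.

    ``config`` must name the input paths (pedigree, gen, sample, optionally
    strata, external, ct) and an ``out_dir``; all thresholds fall back to
    the defaults in :data:`DEFAULT_CONFIG`.  A stage failure raises, leaving
    the manifest naming the completed stages.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"tool": "triogwas", "version": __version__, "stages": {},
                "parameters": {k: v for k, v in cfg.items()
                               if isinstance(v, (int, float, str, bool, type(None)))}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    data = load_inputs(cfg)
    record("load", inputs={k: _sha256(cfg[k]) for k in ("pedigree", "gen", "sample")},
           n_samples=data.n_samples, n_markers=data.n_markers, n_trios=len(data.trios))

    # --- qc
    hard_call_panel(data, threshold=cfg["hard_call_threshold"])
    incons = mask_mendelian_panel(data)
    keep, report = marker_qc(data, call_rate_threshold=cfg["call_rate_threshold"],
                             maf_report_threshold=cfg["maf_report_threshold"],
                             apply_maf_filter=cfg["apply_maf_filter"])
    _write_tsv(report, out / "qc_report.tsv")
    data = subset_markers(data, keep)
    record("qc", n_markers_kept=int(keep.sum()),
           n_mendelian_inconsistencies=int(incons.sum()),
           artifact="qc_report.tsv")

    # --- tdt, both modes
    hard = tdt_scan(data, mode="hard", one_per_family=cfg["one_per_family"])
    expected = tdt_scan(data, mode="expected", one_per_family=cfg["one_per_family"])
    _write_tsv(hard, out / "tdt_hard.tsv")
    _write_tsv(expected, out / "tdt_expected.tsv")
    record("tdt", artifacts=["tdt_hard.tsv", "tdt_expected.tsv"])

    # --- stratified
    if cfg["stratified"]:
        if "strata" not in cfg:
            raise ValueError("stratified mode requested but no 'strata' file configured")
        attach_strata(data, cfg["strata"])
        strat = stratified_scan(data, one_per_family=cfg["one_per_family"])
        _write_tsv(strat, out / "tdt_stratified.tsv")
        record("stratify", artifact="tdt_stratified.tsv",
               inputs={"strata": _sha256(cfg["strata"])})

    # --- selection (expected-count TDT is the default evidence)
    thresholds = SelectionThresholds(**cfg["selection"])
    results = expected
    if cfg["exclude_hla"]:
        results = exclude_hla(results)
    external = pd.read_csv(cfg["external"], sep="\t") if cfg.get("external") else None
    sel = select_markers(results, external, thresholds)
    _write_tsv(sel, out / "selected.tsv")
    chosen = sel[sel["selected"]]
    regions = build_regions(chosen, gap=thresholds.region_gap)
    _write_tsv(regions, out / "regions.tsv")
    record("select", n_selected=int(sel["selected"].sum()), n_regions=len(regions),
           artifacts=["selected.tsv", "regions.tsv"])

    # --- interaction
    pairs = cross_region_pairs(list(chosen["SNP"]), region_of_marker(regions))
    inter = analyze_pairs(data, pairs, min_families=cfg["min_families"],
                          n_restarts=cfg["n_restarts"], seed=cfg["seed"])
    _write_tsv(inter, out / "interaction.tsv")
    record("interact", n_pairs_tested=len(inter), artifact="interaction.tsv")

    # --- expression
    if cfg["expression"]:
        if "ct" not in cfg:
            raise ValueError("expression mode requested but no 'ct' file configured")
        ct = pd.read_csv(cfg["ct"], sep="\t")
        expr = ddct_analysis(ct, cfg["reference_genes"], test=cfg["expression_test"],
                             bonferroni_m=cfg["bonferroni_m"])
        _write_tsv(expr, out / "expression.tsv")
        record("express", artifact="expression.tsv", inputs={"ct": _sha256(cfg["ct"])})

    return out
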