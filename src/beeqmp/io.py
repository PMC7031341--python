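"""Readers and writers for the pipeline's TSV interchange tables.

All tables are tab-separated with a header row; values round-trip at full
double precision (pandas writes shortest round-trip representations).
Validation happens at load time and reports offending identifiers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import LoadError
from .profiles import RRNA_LOCI, included_range
from .qpcr import StandardCurve, fit_standard_curve

__all__ = [
    "read_cq_table",
    "read_standards",
    "read_counts",
    "read_taxonomy",
    "read_metadata",
    "read_curve_config",
    "fit_curves_from_standards",
    "write_curves",
    "read_curves",
    "write_table",
]

#: tokens accepted as "undetected" in Cq columns
NA_TOKENS = ["", "NA", "NaN", "nan", "Undetermined"]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _require(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing column(s) {sorted(missing)}")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Cq measurements: sample_id, target_id, replicate, cq (float or NA)."""
    df = pd.read_csv(path, sep="\t", na_values=NA_TOKENS, keep_default_na=True)
    _require(df, {"sample_id", "target_id", "cq"}, path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    detected = df["cq"].dropna()
    bad = detected[detected <= 0]
    if len(bad):
        raise LoadError(f"{path}: nonpositive Cq at line(s) {(bad.index + 2).tolist()[:5]}")
    dup = df.duplicated(["sample_id", "target_id", "replicate"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise LoadError(
            f"{path}: duplicate measurement for sample {first['sample_id']!r} "
            f"target {first['target_id']!r} replicate {first['replicate']!r}"
        )
    return df


def read_standards(path: str | Path) -> pd.DataFrame:
    """Dilution series: target_id, copies_per_ul, cq (one row per well)."""
    df = pd.read_csv(path, sep="\t", na_values=NA_TOKENS)
    _require(df, {"target_id", "copies_per_ul", "cq"}, path)
    if (df["copies_per_ul"] <= 0).any():
        raise LoadError(f"{path}: copies_per_ul must be positive")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """ASV count matrix: first column taxon_id, one column per sample."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise LoadError(f"{path}: duplicated sample_id {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicated taxon_id {dup}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.isnan(arr.astype(float)).any():
        raise LoadError(f"{path}: count matrix has non-numeric or missing cells")
    if (arr < 0).any():
        t, s = np.argwhere(arr < 0)[0]
        raise LoadError(
            f"{path}: negative count for taxon {df.index[t]!r} sample {df.columns[s]!r}"
        )
    return df.astype(int)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxon annotations: taxon_id, phylotype, category, excluded_reason, rrna_loci."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKENS)
    _require(df, {"phylotype", "category", "rrna_loci"}, path)
    if "excluded_reason" not in df.columns:
        df["excluded_reason"] = ""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicated taxon_id {dup}")
    excluded = df["category"] == "excluded"
    missing_reason = excluded & df["excluded_reason"].fillna("").eq("")
    if missing_reason.any():
        raise LoadError(
            f"{path}: excluded taxa without a reason: {sorted(df.index[missing_reason])}"
        )
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata keyed by sample_id (bee type, hive, treatment, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKENS)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicated sample_id {dup}")
    return df


def read_curve_config(path: str | Path) -> dict[str, dict]:
    """Per-target curve configuration from YAML.

    Keys per target: lod_copies, included_range ([min, max]), rrna_loci,
    report_nabs. Missing keys fall back to the shipped defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise LoadError(f"{path}: curve config must be a mapping target -> options")
    return cfg


def fit_curves_from_standards(
    standards: pd.DataFrame, config: Mapping[str, Mapping] | None = None
) -> dict[str, StandardCurve]:
    """Fit one standard curve per target in a standards table.

    ``config`` overrides LOD, included dilution range, operon number and the
    universal-assay reporting flag per target; defaults mirror the shipped
    assay panel where the target is known, else LOD 100 and loci 1.
    """
    config = config or {}
    curves = {}
    for tid, grp in standards.groupby("target_id"):
        opts = dict(config.get(tid, {}))
        try:
            default_rng = included_range(tid)
            default_lod = default_rng[0]
        except KeyError:
            default_rng, default_lod = None, 100.0
        rng = opts.get("included_range", default_rng)
        curves[tid] = fit_standard_curve(
            grp.rename(columns={"copies_per_ul": "copies_per_ul"}),
            target_id=tid,
            lod_copies=float(opts.get("lod_copies", default_lod)),
            included_range=tuple(rng) if rng is not None else None,
            rrna_loci=int(opts.get("rrna_loci", RRNA_LOCI.get(tid, 1))),
            report_nabs=bool(opts.get("report_nabs", tid == "universal_16s")),
        )
    return curves


def write_curves(curves: Mapping[str, StandardCurve], path: str | Path) -> None:
    rows = [
        dict(
            target_id=c.target_id,
            slope=c.slope,
            intercept=c.intercept,
            efficiency=c.efficiency,
            lod_copies=c.lod_copies,
            lod_cq=c.lod_cq,
            rrna_loci=c.rrna_loci,
            report_nabs=c.report_nabs,
        )
        for c in curves.values()
    ]
    write_table(pd.DataFrame(rows), path)


def read_curves(path: str | Path) -> dict[str, StandardCurve]:
    df = pd.read_csv(path, sep="\t")
    _require(df, {"target_id", "slope", "intercept", "lod_copies", "rrna_loci"}, path)
    out = {}
    for _, r in df.iterrows():
        out[r["target_id"]] = StandardCurve(
            target_id=r["target_id"],
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            lod_copies=float(r["lod_copies"]),
            rrna_loci=int(r["rrna_loci"]),
            report_nabs=bool(r.get("report_nabs", False)),
        )
    return out
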