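"""Full-analysis orchestration: curves -> quantify -> QMP -> diversity -> stats.

:func:`run_pipeline` executes the published analysis order on a set of input
tables and writes every intermediate plus a run manifest (configuration echo,
seed, package versions, input checksums), making reruns byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import alpha_diversity, bray_curtis, dispersion, log_transform, pca, permanova
from .errors import BeeQmpError, ConfigError
from .io import (
    fit_curves_from_standards,
    read_cq_table,
    read_counts,
    read_curve_config,
    read_metadata,
    read_standards,
    read_taxonomy,
    write_curves,
    write_table,
)
from .permstats import perm_test, tukey_hsd
from .profiles import SEVEN_PHYLOTYPES
from .qmp import qmp_pipeline
from .qpcr import quantify, summed_load

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    standards: str
    cq_table: str
    counts: str
    taxonomy: str
    metadata: str
    seed: int
    curve_config: str | None = None  # YAML path with per-target overrides
    group_column: str = "bee_type"
    permutations: int = 10_000
    permanova_permutations: int = 999
    alpha: float = 0.05
    filter_min_samples: int = 2
    filter_min_total: int = 10
    pca_scale: bool = False
    median_actin: float | None = None

    def __post_init__(self) -> None:
        if self.permutations < 1 or self.permanova_permutations < 1:
            raise ConfigError("permutation counts must be >= 1")
        if self.seed is None:
            raise ConfigError("seed must be set explicitly")
        if self.filter_min_samples < 0 or self.filter_min_total < 0:
            raise ConfigError("filter thresholds must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except BeeQmpError as exc:
                raise BeeQmpError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the analysis end to end and write the result bundle.

    Outputs under ``outdir``: curves.tsv, abundances.tsv, qmp.tsv,
    diversity.tsv, permanova.tsv, dispersion.tsv, pca_scores.tsv, stats.tsv,
    pairwise.tsv and manifest.json. Returns the bundle in memory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    inputs = {
        "standards": config.standards,
        "cq_table": config.cq_table,
        "counts": config.counts,
        "taxonomy": config.taxonomy,
        "metadata": config.metadata,
    }

    standards = _stage("load")(read_standards)(config.standards)
    cq_table = _stage("load")(read_cq_table)(config.cq_table)
    counts = _stage("load")(read_counts)(config.counts)
    taxonomy = _stage("load")(read_taxonomy)(config.taxonomy)
    metadata = _stage("load")(read_metadata)(config.metadata)
    curve_cfg = read_curve_config(config.curve_config) if config.curve_config else None

    curves = _stage("curves")(fit_curves_from_standards)(standards, curve_cfg)
    write_curves(curves, outdir / "curves.tsv")

    abundances = _stage("quantify")(quantify)(
        cq_table, curves, median_actin=config.median_actin
    )
    write_table(abundances, outdir / "abundances.tsv")

    # universal-assay total 16S copies per gut feed the QMP conversion
    universal = abundances[abundances["target_id"] == "universal_16s"]
    total_16s = universal.set_index("sample_id")["n_abs"]
    amplicon_samples = [s for s in counts.columns if s in total_16s.index]
    if not amplicon_samples:
        raise BeeQmpError(
            "stage 'qmp' failed: no amplicon sample has a universal 16S measurement"
        )
    qmp = _stage("qmp")(qmp_pipeline)(
        counts[amplicon_samples],
        taxonomy,
        total_16s,
        min_samples=config.filter_min_samples,
        min_total=config.filter_min_total,
    )
    write_table(qmp.to_long(), outdir / "qmp.tsv")

    diversity = _stage("diversity")(alpha_diversity)(qmp.abs_ge)
    write_table(diversity.reset_index(), outdir / "diversity.tsv")

    groups = metadata.loc[qmp.abs_ge.index, config.group_column]
    dm = bray_curtis(qmp.abs_ge)
    perm = _stage("diversity")(permanova)(
        dm, groups.to_numpy(), config.permanova_permutations, rng_seed
    )
    write_table(
        pd.DataFrame(
            [dict(test="permanova", metric="bray_curtis", group=config.group_column,
                  pseudo_F=perm.observed, permutations=perm.n_permutations,
                  exceed_count=perm.exceed_count, p=perm.p, seed=rng_seed)]
        ),
        outdir / "permanova.tsv",
    )
    disp = _stage("diversity")(dispersion)(
        dm, groups.to_numpy(), config.permanova_permutations, rng_seed
    )
    disp_df = pd.DataFrame(
        {"sample_id": qmp.abs_ge.index, "group": groups.to_numpy(),
         "dist_to_centroid": disp.distances.to_numpy()}
    )
    disp_df["F"] = disp.statistic
    disp_df["p"] = disp.p
    write_table(disp_df, outdir / "dispersion.tsv")

    # PCA on log10 absolute phylotype abundances from the qPCR assays
    ge_wide = (
        abundances[abundances["target_id"].isin(SEVEN_PHYLOTYPES)]
        .pivot(index="sample_id", columns="target_id", values="n_ge")
        .fillna(0.0)
    )
    ordination = _stage("diversity")(pca)(log_transform(ge_wide), scale=config.pca_scale)
    scores = ordination.scores.copy()
    scores.insert(0, "sample_id", scores.index)
    write_table(scores, outdir / "pca_scores.tsv")

    # omnibus + pairwise statistics on the total load
    total = summed_load(abundances, SEVEN_PHYLOTYPES)
    stat_groups = metadata.loc[total.index, config.group_column]
    res = _stage("stats")(perm_test)(
        total.to_numpy(), stat_groups.to_numpy(), "anova_F", config.permutations, rng_seed
    )
    write_table(
        pd.DataFrame(
            [dict(response="total_ge", grouping=config.group_column,
                  statistic=res.statistic_name, observed=res.observed,
                  permutations=res.n_permutations, p=res.p, seed=rng_seed)]
        ),
        outdir / "stats.tsv",
    )
    pairs = _stage("stats")(tukey_hsd)(total.to_numpy(), stat_groups.to_numpy())
    write_table(
        pd.DataFrame([p.__dict__ for p in pairs]), outdir / "pairwise.tsv"
    )

    manifest = {
        "package": "beeqmp",
        "version": __version__,
        "seed": rng_seed,
        "config": {k: v for k, v in config.__dict__.items()},
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "curves": curves,
        "abundances": abundances,
        "qmp": qmp,
        "diversity": diversity,
        "permanova": perm,
        "dispersion": disp,
        "pca": ordination,
        "stats": res,
        "pairwise": pairs,
        "manifest": manifest,
    }
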