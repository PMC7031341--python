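"""Synthetic honeybee gut communities and the measurements taken on them.

The generators are the exact stochastic inverse of the analysis chain, so
every pipeline stage can be tested for parameter recovery without any
download:

* :func:`gen_hive` draws per-bee ground-truth genome equivalents (GE) from
  per-bee-type lognormal load profiles with Bernoulli colonization;
* :func:`gen_cq` inverts the qPCR chain (actin normalization included) and
  emits noisy Cq tables — at ``sigma_cq=0`` the quantification chain returns
  the true GE exactly;
* :func:`gen_amplicon` draws multinomial reads with 16S-operon-weighted
  probabilities plus off-target (organelle) and spurious rare ASVs, and
  reports the matching universal-assay total 16S copy number;
* :func:`gen_colonization` simulates the sugar-water vs sugar-water+pollen
  gnotobiotic experiment, including the gut-weight/load rank correlation.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .profiles import (
    MINOR_TAXA,
    RRNA_LOCI,
    SEVEN_PHYLOTYPES,
    BeeTypeProfile,
    ColonizationConfig,
    colonization_anchors,
    default_curves,
    paper_anchors,
)
from .qpcr import EXTRACT_VOLUME_UL, StandardCurve

__all__ = [
    "META_COLS",
    "ge_matrix",
    "gen_hive",
    "gen_cq",
    "gen_amplicon",
    "gen_colonization",
    "gen_standards",
    "pool_bees",
    "truth_long",
    "SimulatedAmplicon",
]

#: non-abundance columns of a simulated-bee frame
META_COLS = ["bee_type", "hive", "treatment", "gut_weight_mg", "actin_copies"]


def ge_matrix(bees: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth genome equivalents: samples x taxa (meta columns dropped)."""
    return bees[[c for c in bees.columns if c not in META_COLS]]


def _draw_bees(
    profile: BeeTypeProfile,
    n: int,
    rng: np.random.Generator,
    taxa: Sequence[str],
    ids: Sequence[str],
) -> pd.DataFrame:
    ge = np.zeros((n, len(taxa)))
    for j, taxon in enumerate(taxa):
        tp = profile.taxa.get(taxon)
        if tp is None:
            continue
        colonized = rng.random(n) < tp.detectability
        loads = 10.0 ** rng.normal(tp.log10_mean, tp.log10_sd, size=n)
        ge[:, j] = np.where(colonized, loads, 0.0)
    gut = np.clip(
        rng.normal(profile.gut_weight_mean_mg, profile.gut_weight_sd_mg, size=n), 1.0, None
    )
    actin = 10.0 ** rng.normal(profile.actin_log10_mean, profile.actin_log10_sd, size=n)
    out = pd.DataFrame(ge, columns=list(taxa), index=list(ids))
    out.insert(0, "bee_type", profile.bee_type)
    out.insert(1, "gut_weight_mg", gut)
    out.insert(2, "actin_copies", actin)
    out.index.name = "sample_id"
    return out


def gen_hive(
    profiles: Mapping[str, BeeTypeProfile] | None = None,
    n_per_type: int = 100,
    seed: int | np.random.Generator | None = None,
    n_hives: int = 1,
) -> pd.DataFrame:
    """Simulate individual worker bees for each bee type.

    Returns a frame indexed by sample_id with meta columns (``bee_type``,
    ``hive``, ``gut_weight_mg``, ``actin_copies``) and one GE column per
    taxon. Bees are spread evenly over ``n_hives`` hives.
    """
    if n_per_type < 1:
        raise ConfigError("n_per_type must be >= 1")
    profiles = paper_anchors() if profiles is None else profiles
    rng = np.random.default_rng(seed)
    taxa = sorted({t for p in profiles.values() for t in p.taxa})
    frames = []
    for bt, profile in profiles.items():
        ids = [f"{bt}_{i:04d}" for i in range(n_per_type)]
        df = _draw_bees(profile, n_per_type, rng, taxa, ids)
        df.insert(1, "hive", [f"hive{(i % n_hives) + 1:02d}" for i in range(n_per_type)])
        frames.append(df)
    return pd.concat(frames)


def truth_long(bees: pd.DataFrame) -> pd.DataFrame:
    """Tidy ground truth: one row per (sample, taxon) with the true GE."""
    long = ge_matrix(bees).stack().rename("true_ge").reset_index()
    long.columns = ["sample_id", "taxon", "true_ge"]
    return long


def gen_cq(
    bees: pd.DataFrame,
    curves: Mapping[str, StandardCurve] | None = None,
    sigma_cq: float = 0.1,
    seed: int | np.random.Generator | None = None,
    n_replicates: int = 2,
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Emit a long-format Cq table for the qPCR assay panel.

    The template concentration seen by the assay inverts the normalization
    chain exactly: ``copies_per_ul = GE * loci * actin / (median(actin) *
    extract_volume)``; the universal assay sees the 16S copy sum of the whole
    community. Gaussian noise of sd ``sigma_cq`` cycles is added per
    technical replicate. True zeros are emitted as undetected (NaN); signals
    beyond the LOD are emitted as their Cq value and censored downstream.
    """
    curves = default_curves() if curves is None else curves
    if targets is None:
        targets = [t for t in SEVEN_PHYLOTYPES if t in curves] + ["universal_16s"]
    missing = [t for t in list(targets) + ["actin"] if t not in curves]
    if missing:
        raise ConfigError(f"no standard curve for simulated target(s): {missing}")
    rng = np.random.default_rng(seed)
    ge = ge_matrix(bees)
    median_actin = float(np.median(bees["actin_copies"]))
    rows = []

    def emit(sample_id, target_id, copies_ul):
        curve = curves[target_id]
        for rep in range(1, n_replicates + 1):
            if copies_ul <= 0:
                cq = float("nan")
            else:
                cq = curve.cq_of(copies_ul) + (rng.normal(0.0, sigma_cq) if sigma_cq else 0.0)
            rows.append((sample_id, target_id, rep, cq))

    loci = {t: curves[t].rrna_loci if t in curves else RRNA_LOCI.get(t, 1) for t in ge.columns}
    for sid, bee in bees.iterrows():
        scale = bee["actin_copies"] / (median_actin * EXTRACT_VOLUME_UL)
        for target in targets:
            if target == "universal_16s":
                n_abs = sum(bee[t] * loci[t] for t in ge.columns)
            else:
                n_abs = bee[target] * curves[target].rrna_loci
            emit(sid, target, n_abs * scale)
        emit(sid, "actin", bee["actin_copies"])
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "replicate", "cq"])


@dataclass(frozen=True)
class SimulatedAmplicon:
    """Amplicon sequencing output: ASV counts, annotations, total 16S load."""

    counts: pd.DataFrame  # ASVs x samples, integer reads
    taxonomy: pd.DataFrame  # ASV annotations (phylotype, category, ..., rrna_loci)
    total_16s: pd.Series  # universal-assay 16S copies per sample

    # split fractions used for multi-ASV phylotypes (documented for tests)
    ASV_SPLIT = (0.7, 0.3)


def gen_amplicon(
    bees: pd.DataFrame,
    depth: int = 27_000,
    seed: int | np.random.Generator | None = None,
    *,
    offtarget_frac: float = 0.02,
    split_asvs: bool = True,
    spurious_rate: float = 0.05,
    total_16s_noise_sd: float = 0.0,
    rrna_loci: Mapping[str, int] | None = None,
) -> SimulatedAmplicon:
    """Multinomial read sampling from the true community.

    Read probabilities are proportional to GE x 16S operon number, so taxa
    with more operons are over-represented in reads exactly as in real
    amplicon data. ``offtarget_frac`` of reads go to host mitochondria /
    chloroplast ASVs (removed by the exclusion stage); two spurious rare ASVs
    receive ~``spurious_rate`` expected reads per sample (removed by the
    abundance filter). Major phylotypes are split into two ASVs to exercise
    phylotype collapsing. ``total_16s`` is the exact 16S copy sum, optionally
    with lognormal noise of the given log10 sd.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    if not (0.0 <= offtarget_frac < 1.0):
        raise ConfigError("offtarget_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    loci = dict(RRNA_LOCI) if rrna_loci is None else dict(rrna_loci)
    ge = ge_matrix(bees)
    taxa = list(ge.columns)
    unknown = [t for t in taxa if t not in loci]
    if unknown:
        raise ConfigError(f"no rRNA operon number for simulated taxa: {unknown}")

    # ASV layout
    rows = []  # (asv_id, phylotype, category, excluded_reason, loci, split_frac)
    core = set(SEVEN_PHYLOTYPES[:5])
    for t in taxa:
        cat = "core" if t in core else ("noncore" if t in SEVEN_PHYLOTYPES else "minor")
        fracs = SimulatedAmplicon.ASV_SPLIT if (split_asvs and t in SEVEN_PHYLOTYPES) else (1.0,)
        for k, f in enumerate(fracs, 1):
            rows.append((f"asv_{t}_{k}", t, cat, "", loci[t], f))
    rows.append(("asv_host_mito", "host_mitochondria", "excluded", "mitochondria", 1, 1.0))
    rows.append(("asv_plant_chloro", "plant_chloroplast", "excluded", "chloroplast", 1, 1.0))
    rows.append(("asv_spurious_1", "enterobacteriaceae_sp1", "minor", "", 7, 1.0))
    rows.append(("asv_spurious_2", "enterobacteriaceae_sp2", "minor", "", 7, 1.0))
    layout = pd.DataFrame(
        rows, columns=["asv_id", "phylotype", "category", "excluded_reason", "rrna_loci", "split"]
    ).set_index("asv_id")

    spur_frac = min(spurious_rate / depth, 0.01)
    bact_mass = 1.0 - offtarget_frac - 2 * spur_frac
    counts = np.zeros((len(layout), len(bees)), dtype=int)
    total_16s = np.zeros(len(bees))
    bact_rows = layout["category"] != "excluded"
    is_spur = layout.index.str.startswith("asv_spurious")
    for s, (sid, bee) in enumerate(bees.iterrows()):
        w = np.zeros(len(layout))
        for i, (asv, row) in enumerate(layout.iterrows()):
            t = row["phylotype"]
            if t in taxa:
                w[i] = bee[t] * row["rrna_loci"] * row["split"]
        wsum = w.sum()
        if wsum <= 0:
            raise ConfigError(f"sample {sid!r} has an all-zero community")
        p = w / wsum * bact_mass
        p[layout.index.get_loc("asv_host_mito")] = offtarget_frac / 2
        p[layout.index.get_loc("asv_plant_chloro")] = offtarget_frac / 2
        p[is_spur] = spur_frac
        counts[:, s] = rng.multinomial(depth, p / p.sum())
        total_16s[s] = sum(bee[t] * loci[t] for t in taxa)
    if total_16s_noise_sd:
        total_16s = total_16s * 10.0 ** rng.normal(0.0, total_16s_noise_sd, size=len(bees))
    return SimulatedAmplicon(
        counts=pd.DataFrame(counts, index=layout.index, columns=bees.index),
        taxonomy=layout.drop(columns="split"),
        total_16s=pd.Series(total_16s, index=bees.index, name="total_16s"),
    )


def pool_bees(
    bees: pd.DataFrame,
    guts_per_pool: int = 20,
    by: Sequence[str] = ("hive", "bee_type"),
) -> pd.DataFrame:
    """Pool consecutive guts within each group by equal-mass averaging.

    Mirrors pooled sampling designs (e.g. 20 guts per bee type per hive):
    GE, gut weight and actin are arithmetic means over each pool. Incomplete
    trailing pools are kept (they average fewer guts).
    """
    by = [c for c in by if c in bees.columns]
    num_cols = [c for c in bees.columns if c not in ("bee_type", "hive", "treatment")]
    pooled = []
    for key, grp in bees.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for k, start in enumerate(range(0, len(grp), guts_per_pool), 1):
            chunk = grp.iloc[start : start + guts_per_pool]
            rec = dict(zip(by, key))
            rec["sample_id"] = "_".join([*map(str, key), f"pool{k:02d}"])
            for c in num_cols:
                rec[c] = float(chunk[c].mean())
            pooled.append(rec)
    return pd.DataFrame(pooled).set_index("sample_id")


def gen_colonization(
    config: ColonizationConfig | None = None,
    n_per_arm: int = 100,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the gnotobiotic SW vs SW+P colonization experiment.

    Within each arm a latent per-bee factor couples gut weight and all
    log10 loads through a Gaussian copula so that Spearman(gut weight, total
    load) approaches ``config.weight_load_spearman``; setting it to 0 makes
    them independent.
    """
    if n_per_arm < 1:
        raise ConfigError("n_per_arm must be >= 1")
    config = colonization_anchors() if config is None else config
    rng = np.random.default_rng(seed)
    rho = config.weight_load_spearman
    # Pearson correlation of the latent normals giving the target Spearman
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    a = math.sqrt(abs(r))
    sign = 1.0 if r >= 0 else -1.0
    taxa = sorted({t for p in config.arms.values() for t in p.taxa})
    frames = []
    for arm, profile in config.arms.items():
        n = n_per_arm
        z = rng.normal(size=n)  # shared gut-size factor
        gut_latent = sign * a * z + math.sqrt(max(0.0, 1 - a * a)) * rng.normal(size=n)
        ge = np.zeros((n, len(taxa)))
        for j, taxon in enumerate(taxa):
            tp = profile.taxa.get(taxon)
            if tp is None:
                continue
            colonized = rng.random(n) < tp.detectability
            eps = rng.normal(size=n)
            log_load = tp.log10_mean + tp.log10_sd * (
                a * z + math.sqrt(max(0.0, 1 - a * a)) * eps
            )
            ge[:, j] = np.where(colonized, 10.0 ** log_load, 0.0)
        gut = np.clip(
            profile.gut_weight_mean_mg + profile.gut_weight_sd_mg * gut_latent, 1.0, None
        )
        actin = 10.0 ** rng.normal(profile.actin_log10_mean, profile.actin_log10_sd, size=n)
        safe = arm.replace("+", "p").lower()
        df = pd.DataFrame(ge, columns=taxa, index=[f"{safe}_{i:04d}" for i in range(n)])
        df.insert(0, "bee_type", arm)
        df.insert(1, "treatment", arm)
        df.insert(2, "gut_weight_mg", gut)
        df.insert(3, "actin_copies", actin)
        df.index.name = "sample_id"
        frames.append(df)
    return pd.concat(frames)


def gen_standards(
    curves: Mapping[str, StandardCurve] | None = None,
    sigma_cq: float = 0.05,
    seed: int | np.random.Generator | None = None,
    n_replicates: int = 3,
    dilutions: Sequence[float] = tuple(10.0 ** k for k in range(1, 8)),
) -> pd.DataFrame:
    """Simulate plasmid serial-dilution runs for every assay in the panel.

    Returns the standards table (target_id, copies_per_ul, cq) from which the
    `curves` stage refits slopes and intercepts.
    """
    curves = default_curves() if curves is None else curves
    rng = np.random.default_rng(seed)
    rows = []
    for tid, curve in curves.items():
        for c in dilutions:
            for _ in range(n_replicates):
                cq = curve.cq_of(c) + (rng.normal(0.0, sigma_cq) if sigma_cq else 0.0)
                rows.append((tid, c, cq))
    return pd.DataFrame(rows, columns=["target_id", "copies_per_ul", "cq"])
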