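"""Quantitative microbiome profiling of amplicon count tables.

Turns an annotated ASV count matrix (taxa x samples) into absolute per-taxon
genome equivalents per gut, using the total 16S rRNA gene copy number of each
sample measured by universal qPCR:

1. drop off-target reads (mitochondria, chloroplast, eukaryotes);
2. abundance filter: keep taxa present in >= 2 samples with >= 10 total reads;
3. collapse ASVs into phylotypes;
4. per-sample proportions over the retained community;
5. absolute abundance: ``abs_ge[s, t] = prop[s, t] * total_16s[s] / loci[t]``.

The stage order is part of the method: filtering acts on ASVs before
phylotype collapsing, and proportions are renormalized over retained taxa.
A taxon with zero reads in a sample is below the detection limit of amplicon
sequencing and gets ``abs_ge = 0`` there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError, DepthError

__all__ = [
    "exclude_off_target",
    "abundance_filter",
    "collapse_phylotypes",
    "proportions",
    "to_absolute",
    "QmpMatrix",
    "qmp_pipeline",
]

VALID_CATEGORIES = {"core", "noncore", "minor", "excluded"}


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise AnnotationError("duplicate taxon identifiers in count matrix")
    if counts.columns.has_duplicates:
        raise AnnotationError("duplicate sample identifiers in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative values")


def exclude_off_target(counts: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Remove taxa annotated as excluded (mitochondria/chloroplast/eukaryote)."""
    _check_counts(counts)
    unannotated = counts.index.difference(annotations.index)
    if len(unannotated):
        raise AnnotationError(f"unannotated taxa: {sorted(unannotated)}")
    ann = annotations.loc[counts.index]
    bad_cat = set(ann["category"]) - VALID_CATEGORIES
    if bad_cat:
        raise AnnotationError(f"unknown taxon categories: {sorted(bad_cat)}")
    keep = ann["category"] != "excluded"
    out = counts.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("all taxa excluded as off-target; matrix is empty", stacklevel=2)
    return out


def abundance_filter(
    counts: pd.DataFrame, min_samples: int = 2, min_total: int = 10
) -> pd.DataFrame:
    """Keep taxa present in >= ``min_samples`` samples AND with >= ``min_total`` reads.

    The two predicates are a conjunction of prevalence and total abundance,
    both evaluated on the raw per-ASV counts.
    """
    _check_counts(counts)
    prevalence = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    return counts.loc[(prevalence >= min_samples) & (total >= min_total)]


def collapse_phylotypes(counts: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Sum ASV counts into phylotype-level counts per sample (totals conserved)."""
    _check_counts(counts)
    missing = counts.index.difference(annotations.index)
    if len(missing):
        raise AnnotationError(f"taxa without annotation: {sorted(missing)}")
    labels = annotations.loc[counts.index, "phylotype"]
    if labels.isna().any():
        raise AnnotationError(
            f"taxa without phylotype label: {sorted(counts.index[labels.isna()])}"
        )
    collapsed = counts.groupby(labels).sum()
    collapsed.index.name = "phylotype"
    return collapsed


def proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances over the retained taxa (columns sum to 1)."""
    _check_counts(counts)
    depth = counts.sum(axis=0)
    empty = depth[depth <= 0]
    if len(empty):
        raise DepthError(f"zero sequencing depth in sample(s): {sorted(empty.index)}")
    return counts / depth


@dataclass(frozen=True)
class QmpMatrix:
    """Absolute community profile: samples x phylotypes genome equivalents.

    ``abs_ge`` has samples as rows and phylotypes as columns; ``total_16s``
    is the universal-assay 16S copy number per gut used for the scaling.
    The defining identity ``sum_t abs_ge[s,t] * loci[t] == total_16s[s]``
    holds to numerical precision.
    """

    abs_ge: pd.DataFrame
    total_16s: pd.Series
    rrna_loci: pd.Series

    def proportions(self) -> pd.DataFrame:
        """Reconstruct the input proportions: ``abs_ge * loci / total_16s``."""
        expected = self.abs_ge * self.rrna_loci
        return expected.div(self.total_16s, axis=0)

    def to_long(self) -> pd.DataFrame:
        """Tidy output: sample_id, phylotype, proportion, abs_ge, total_16s."""
        props = self.proportions()
        long = self.abs_ge.stack().rename("abs_ge").reset_index()
        long.columns = ["sample_id", "phylotype", "abs_ge"]
        long["proportion"] = props.stack().to_numpy()
        long["total_16s"] = long["sample_id"].map(self.total_16s)
        return long[["sample_id", "phylotype", "proportion", "abs_ge", "total_16s"]]


def to_absolute(
    props: pd.DataFrame,
    total_16s: pd.Series,
    rrna_loci: pd.Series | dict,
) -> QmpMatrix:
    """Scale proportions by total 16S load and correct for operon copy number.

    ``props`` is taxa x samples (as produced by :func:`proportions`);
    ``total_16s`` maps sample -> universal-assay 16S copies per gut;
    ``rrna_loci`` maps phylotype -> 16S operons per genome.
    """
    rrna_loci = pd.Series(rrna_loci, dtype=float)
    missing_loci = props.index.difference(rrna_loci.index)
    if len(missing_loci):
        raise AnnotationError(f"no rRNA operon number for: {sorted(missing_loci)}")
    missing_tot = props.columns.difference(total_16s.index)
    if len(missing_tot):
        raise ValueError(f"no total 16S measurement for sample(s): {sorted(missing_tot)}")
    tot = total_16s.loc[props.columns].astype(float)
    if (tot <= 0).any():
        raise ValueError(
            f"nonpositive total 16S load in sample(s): {sorted(tot.index[tot <= 0])}"
        )
    loci = rrna_loci.loc[props.index]
    if (loci < 1).any():
        raise AnnotationError("rRNA operon numbers must be >= 1")
    abs_ge = (props.mul(tot, axis=1)).div(loci, axis=0)
    return QmpMatrix(abs_ge=abs_ge.T, total_16s=tot, rrna_loci=loci)


def qmp_pipeline(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    total_16s: pd.Series,
    *,
    phylotype_loci: pd.Series | dict | None = None,
    min_samples: int = 2,
    min_total: int = 10,
) -> QmpMatrix:
    """Full conversion: exclusion -> filter -> collapse -> proportions -> absolute.

    ``phylotype_loci`` gives operon numbers at the collapsed phylotype level;
    when omitted it is derived as the per-phylotype mean of the ASV-level
    ``rrna_loci`` annotation (rounded to the nearest integer).
    """
    kept = abundance_filter(
        exclude_off_target(counts, annotations), min_samples, min_total
    )
    collapsed = collapse_phylotypes(kept, annotations)
    if phylotype_loci is None:
        labels = annotations.loc[kept.index, "phylotype"]
        phylotype_loci = (
            annotations.loc[kept.index, "rrna_loci"].astype(float).groupby(labels).mean().round()
        )
    return to_absolute(proportions(collapsed), total_16s, phylotype_loci)
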