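"""qPCR absolute quantification of gut bacteria.

Converts quantification-cycle (Cq) values into absolute abundances per gut:

* a standard curve per target fitted by OLS of Cq on log10(plasmid copies),
  with amplification efficiency ``E = 10**(-1/slope)``;
* raw copies per microlitre of template, ``n_raw = E**(intercept - Cq)``;
* host-gene (actin) normalization to copies per gut,
  ``n_abs = (n_raw / n_actin) * median(n_actin) * extract_volume``;
* genome equivalents, ``n_ge = n_abs / rrna_loci`` (the universal bacterial
  assay is reported as ``n_abs`` because 16S operon number varies between
  community members).

Cq values above a target's limit of detection (LOD) — the Cq of the lowest
quantifiable dilution — are treated as not quantifiable and set to zero
abundance everywhere downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CalibrationError, DegenerateCurveError, SampleFailureError

__all__ = [
    "StandardCurve",
    "efficiency_from_slope",
    "fit_standard_curve",
    "raw_copies",
    "normalize_per_gut",
    "genome_equivalents",
    "quantify",
    "summed_load",
]

#: default DNA extract volume in microlitres (one bee gut resuspended in 200 ul)
EXTRACT_VOLUME_UL = 200.0


def efficiency_from_slope(slope: float) -> float:
    """Per-cycle amplification factor ``E = 10**(-1/slope)``.

    A slope of -3.321928 (one doubling per cycle) gives E = 2.
    """
    if slope >= 0:
        raise CalibrationError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope)


@dataclass(frozen=True)
class StandardCurve:
    """Per-target calibration of a qPCR assay.

    Parameters
    ----------
    target_id : str
        Bacterial target (phylotype), ``actin`` or ``universal_16s``.
    slope, intercept : float
        OLS fit of Cq on log10(copies/ul); the intercept is the Cq
        extrapolated to 1 copy/ul.
    lod_copies : float
        Copies/ul at the limit of detection (typically 10 or 100).
    rrna_loci : int
        16S rRNA operons per genome of the target (1 for non-16S targets).
    report_nabs : bool
        If True, genome equivalents are not meaningful for this assay and
        the quantification chain reports ``n_abs`` instead (universal assay).
    """

    target_id: str
    slope: float
    intercept: float
    lod_copies: float = 100.0
    rrna_loci: int = 1
    report_nabs: bool = False

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(
                f"{self.target_id}: slope must be negative, got {self.slope}"
            )
        e = self.efficiency
        if not (1.0 < e <= 2.5):
            raise CalibrationError(
                f"{self.target_id}: implausible efficiency {e:.3f} (slope {self.slope})"
            )
        if self.lod_copies <= 0:
            raise CalibrationError(f"{self.target_id}: lod_copies must be positive")
        if self.rrna_loci < 1:
            raise CalibrationError(f"{self.target_id}: rrna_loci must be >= 1")

    @property
    def efficiency(self) -> float:
        return efficiency_from_slope(self.slope)

    @property
    def lod_cq(self) -> float:
        """Cq corresponding to ``lod_copies``; larger Cq means below LOD."""
        return self.intercept + self.slope * math.log10(self.lod_copies)

    def cq_of(self, copies_per_ul: float) -> float:
        """Noise-free Cq expected for a given template concentration."""
        return self.intercept + self.slope * math.log10(copies_per_ul)


def fit_standard_curve(
    dilution_series: Sequence[tuple[float, float]] | pd.DataFrame,
    *,
    target_id: str = "target",
    lod_copies: float = 100.0,
    included_range: tuple[float, float] | None = None,
    rrna_loci: int = 1,
    report_nabs: bool = False,
) -> StandardCurve:
    """Fit a standard curve from a serial dilution of known plasmid copies.

    ``dilution_series`` is an iterable of ``(copies_per_ul, cq)`` pairs (or a
    DataFrame with columns ``copies_per_ul``/``cq``); replicate wells are
    passed as separate pairs. Only dilutions inside ``included_range``
    (inclusive) enter the OLS fit — mirroring assays whose lowest dilution is
    indistinguishable from the water control.
    """
    if isinstance(dilution_series, pd.DataFrame):
        pairs = dilution_series[["copies_per_ul", "cq"]].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(dilution_series), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("dilution_series must be (copies_per_ul, cq) pairs")
    copies, cq = pairs[:, 0], pairs[:, 1]
    if np.any(copies <= 0):
        raise CalibrationError("plasmid copy numbers must be positive")
    if included_range is not None:
        lo, hi = included_range
        keep = (copies >= lo) & (copies <= hi)
        copies, cq = copies[keep], cq[keep]
    if np.unique(copies).size < 3:
        raise DegenerateCurveError(
            f"{target_id}: need >=3 distinct dilution levels in the included "
            f"range, got {np.unique(copies).size}"
        )
    fit = sps.linregress(np.log10(copies), cq)
    if fit.slope >= 0:
        raise CalibrationError(f"{target_id}: fitted slope {fit.slope:.3f} is not negative")
    return StandardCurve(
        target_id=target_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        lod_copies=lod_copies,
        rrna_loci=rrna_loci,
        report_nabs=report_nabs,
    )


def raw_copies(curve: StandardCurve, cq: float, target_id: str | None = None) -> tuple[float, bool]:
    """Convert one (replicate-averaged) Cq into raw copies/ul.

    Returns ``(n_raw, below_lod)``. Undetected (NaN) Cq and Cq beyond the
    LOD Cq both yield ``(0.0, True)``.
    """
    if target_id is not None and target_id != curve.target_id:
        raise ValueError(f"curve is for {curve.target_id!r}, measurement for {target_id!r}")
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return 0.0, True
    if cq > curve.lod_cq:
        return 0.0, True
    return curve.efficiency ** (curve.intercept - cq), False


def normalize_per_gut(
    n_raw: float,
    n_actin: float,
    median_actin: float,
    extract_volume_ul: float = EXTRACT_VOLUME_UL,
) -> float:
    """Actin-normalized copies per gut: ``(n_raw/n_actin) * median_actin * volume``.

    Normalization by the host single-copy actin gene absorbs gut-size and
    DNA-extraction-efficiency variation; rescaling by the batch median keeps
    the result on the copies-per-gut scale.
    """
    if n_actin <= 0 or median_actin <= 0:
        raise SampleFailureError(
            f"actin quantification failed (n_actin={n_actin}, median={median_actin})"
        )
    return (n_raw / n_actin) * median_actin * extract_volume_ul


def genome_equivalents(n_abs: float, rrna_loci: int) -> float:
    """Genome equivalents ``n_ge = n_abs / rrna_loci`` (proxy for cell number)."""
    if rrna_loci < 1:
        raise ValueError(f"rrna_loci must be >= 1, got {rrna_loci}")
    return n_abs / rrna_loci


def _mean_cq(group: pd.Series) -> float:
    """Average technical replicates on the Cq scale; all-undetected -> NaN."""
    detected = group.dropna()
    return float(detected.mean()) if len(detected) else float("nan")


def quantify(
    cq_table: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    *,
    actin_target: str = "actin",
    extract_volume_ul: float = EXTRACT_VOLUME_UL,
    median_actin: float | None = None,
) -> pd.DataFrame:
    """Run the full quantification chain on a long-format Cq table.

    ``cq_table`` needs columns ``sample_id``, ``target_id``, ``cq`` and
    optionally ``replicate``; NaN (or absent) Cq means undetected. Technical
    replicates are averaged on the Cq scale before conversion. The actin
    median is taken over the batch unless ``median_actin`` overrides it
    (e.g. to reproduce a published dataset's normalization).

    Samples whose actin assay is below the LOD are dropped with a warning
    (cannot be normalized); samples with no actin row at all raise
    :class:`~beeqmp.errors.SampleFailureError`.

    Returns a tidy frame with one row per (sample, bacterial target):
    ``sample_id, target_id, n_raw, n_actin, n_abs, n_ge, below_lod``.
    For assays flagged ``report_nabs`` (universal 16S), ``n_ge`` is ``n_abs``.
    """
    required = {"sample_id", "target_id", "cq"}
    if not required.issubset(cq_table.columns):
        raise ValueError(f"cq_table must have columns {sorted(required)}")
    missing = set(cq_table["target_id"]) - set(curves)
    if missing:
        raise ValueError(f"no standard curve for target(s): {sorted(missing)}")

    mean_cqs = (
        cq_table.groupby(["sample_id", "target_id"])["cq"].apply(_mean_cq).reset_index()
    )

    # actin first: raw copies/ul per sample, batch median, sample exclusion
    actin_curve = curves.get(actin_target)
    actin_rows = mean_cqs[mean_cqs["target_id"] == actin_target]
    all_samples = mean_cqs["sample_id"].unique()
    if actin_curve is None or set(actin_rows["sample_id"]) < set(all_samples):
        lacking = sorted(set(all_samples) - set(actin_rows["sample_id"]))
        raise SampleFailureError(
            f"actin assay missing for sample(s): {lacking or 'all'}"
        )
    n_actin = {}
    failed: list[str] = []
    for _, row in actin_rows.iterrows():
        n, below = raw_copies(actin_curve, row["cq"])
        if below or n <= 0:
            failed.append(row["sample_id"])
        else:
            n_actin[row["sample_id"]] = n
    if failed:
        warnings.warn(
            f"excluding {len(failed)} sample(s) with failed actin amplification: "
            f"{sorted(failed)}",
            stacklevel=2,
        )
    if not n_actin:
        raise SampleFailureError("actin amplification failed for every sample")
    med_actin = float(np.median(list(n_actin.values()))) if median_actin is None else median_actin

    records = []
    bact = mean_cqs[(mean_cqs["target_id"] != actin_target)]
    for _, row in bact.iterrows():
        sid, tid = row["sample_id"], row["target_id"]
        if sid not in n_actin:
            continue
        curve = curves[tid]
        n_raw, below = raw_copies(curve, row["cq"])
        if below:
            n_abs = n_ge = 0.0
        else:
            n_abs = normalize_per_gut(n_raw, n_actin[sid], med_actin, extract_volume_ul)
            n_ge = n_abs if curve.report_nabs else genome_equivalents(n_abs, curve.rrna_loci)
        records.append(
            dict(sample_id=sid, target_id=tid, n_raw=n_raw, n_actin=n_actin[sid],
                 n_abs=n_abs, n_ge=n_ge, below_lod=below)
        )
    out = pd.DataFrame.from_records(
        records, columns=["sample_id", "target_id", "n_raw", "n_actin", "n_abs", "n_ge", "below_lod"]
    )
    out.attrs["median_actin"] = med_actin
    return out


def summed_load(
    abundances: pd.DataFrame,
    phylotypes: Iterable[str],
    value: str = "n_ge",
) -> pd.Series:
    """Total bacterial load per sample: sum of per-phylotype genome equivalents.

    Below-LOD targets carry 0 and therefore contribute nothing; phylotypes
    absent from the table count as 0.
    """
    phylotypes = list(phylotypes)
    sub = abundances[abundances["target_id"].isin(phylotypes)]
    total = sub.groupby("sample_id")[value].sum()
    total.name = "total_" + value
    return total.reindex(abundances["sample_id"].unique(), fill_value=0.0)
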