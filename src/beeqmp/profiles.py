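"""Shipped default configuration: assay panel, standard curves, bee-type profiles.

Everything here is configuration, not measurement. The assay panel covers the
seven routinely monitored phylotypes of the adult worker honeybee gut (five
core: Gilliamella, Snodgrassella, Bifidobacterium, Lactobacillus Firm-4,
Lactobacillus Firm-5; two noncore: Frischella, Bartonella), the host actin
normalizer and a universal bacterial 16S assay.

The ``paper_anchors`` profiles encode the published quantitative anchors of
the forager / nurse / winter-bee community structure:

* winter:forager mean total load ratio ~10 (the per-taxon winter means were
  solved analytically so the closed-form lognormal expectation of the summed
  load gives a ratio of ~10);
* 10-100x winter increases of Firm-4, Firm-5, Bifidobacterium and Bartonella,
  a small Snodgrassella increase, unchanged Gilliamella, reduced Frischella;
* Firm-4 detectable in 98.4% of bees; Bartonella and Frischella below the
  detection limit in 5.3% and 26.9% of bees respectively (encoded uniformly
  across bee types: these anchors are study-wide fractions);
* winter bees lose minor/opportunistic taxa (Apibacter, L. kunkeii, ...) and
  gain Commensalibacter.

16S rRNA operon numbers per genome are rrnDB-style placeholder values keyed
by phylotype; replace them with assay-specific numbers via configuration for
real data. Absolute load levels (forager total ~10^7.5 genome equivalents)
are free parameters — only ratios, prevalences and fold-changes are anchored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConfigError
from .qpcr import StandardCurve

__all__ = [
    "TaxonProfile",
    "BeeTypeProfile",
    "SEVEN_PHYLOTYPES",
    "MINOR_TAXA",
    "RRNA_LOCI",
    "default_curves",
    "paper_anchors",
    "colonization_anchors",
]

#: the seven phylotypes monitored by specific qPCR assays
SEVEN_PHYLOTYPES = [
    "gilliamella",
    "snodgrassella",
    "bifidobacterium",
    "lactobacillus_firm4",
    "lactobacillus_firm5",
    "frischella",
    "bartonella",
]

#: minor community members seen only in amplicon data
MINOR_TAXA = [
    "commensalibacter",
    "apibacter",
    "lactobacillus_kunkeii",
    "bombella",
    "klebsiella",
    "serratia",
]

#: 16S rRNA operons per genome (placeholder values in rrnDB's typical range)
RRNA_LOCI: dict[str, int] = {
    "gilliamella": 4,
    "snodgrassella": 4,
    "bifidobacterium": 2,
    "lactobacillus_firm4": 4,
    "lactobacillus_firm5": 4,
    "frischella": 4,
    "bartonella": 2,
    "commensalibacter": 2,
    "apibacter": 3,
    "lactobacillus_kunkeii": 4,
    "bombella": 2,
    "klebsiella": 8,
    "serratia": 7,
}

# slope/intercept per assay; LOD 10^2 copies/ul for the five assays whose
# 10^1 dilution is indistinguishable from water, 10^1 for the rest; the
# included dilution range for curve fitting follows the same split.
_CURVE_PARAMS: dict[str, tuple[float, float, float, tuple[float, float]]] = {
    # target: (slope, intercept, lod_copies, included_range)
    "gilliamella": (-3.45, 38.6, 10.0, (1e1, 1e7)),
    "snodgrassella": (-3.38, 39.2, 100.0, (1e2, 1e7)),
    "bifidobacterium": (-3.50, 38.0, 10.0, (1e1, 1e7)),
    "lactobacillus_firm4": (-3.42, 39.5, 100.0, (1e2, 1e7)),
    "lactobacillus_firm5": (-3.35, 38.9, 100.0, (1e2, 1e7)),
    "frischella": (-3.47, 39.0, 100.0, (1e2, 1e7)),
    "bartonella": (-3.40, 39.8, 100.0, (1e2, 1e7)),
    "universal_16s": (-3.44, 38.5, 10.0, (1e1, 1e7)),
    "actin": (-3.33, 37.5, 10.0, (1e1, 1e7)),
}


def included_range(target_id: str) -> tuple[float, float]:
    """Dilution range (copies/ul) entering the OLS fit for an assay."""
    return _CURVE_PARAMS[target_id][3]


def default_curves() -> dict[str, StandardCurve]:
    """Default standard curves for the full assay panel.

    Slopes correspond to efficiencies of 1.93-2.00. These stand in for
    plate-specific fits; the `curves` CLI stage refits them from a
    standards table.
    """
    out = {}
    for tid, (slope, intercept, lod, _rng) in _CURVE_PARAMS.items():
        out[tid] = StandardCurve(
            target_id=tid,
            slope=slope,
            intercept=intercept,
            lod_copies=lod,
            rrna_loci=RRNA_LOCI.get(tid, 1),
            report_nabs=(tid == "universal_16s"),
        )
    return out


@dataclass(frozen=True)
class TaxonProfile:
    """Lognormal load model of one taxon in one bee type.

    ``detectability`` is the probability that a bee is colonized at all;
    colonized bees carry ``10**Normal(log10_mean, log10_sd)`` genome
    equivalents, non-colonized bees carry exactly 0.
    """

    log10_mean: float
    log10_sd: float
    detectability: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detectability <= 1.0):
            raise ConfigError(f"detectability must be in [0,1], got {self.detectability}")
        if self.log10_sd < 0:
            raise ConfigError(f"log10_sd must be >= 0, got {self.log10_sd}")


@dataclass(frozen=True)
class BeeTypeProfile:
    """Community and host parameters of one bee type (or treatment arm)."""

    bee_type: str
    taxa: Mapping[str, TaxonProfile]
    gut_weight_mean_mg: float = 40.0
    gut_weight_sd_mg: float = 8.0
    actin_log10_mean: float = 4.0  # actin copies per ul of extract
    actin_log10_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.gut_weight_mean_mg <= 0 or self.gut_weight_sd_mg < 0:
            raise ConfigError("gut weight parameters must be positive")


def _profile(bee_type, taxa, gw_mean, gw_sd):
    return BeeTypeProfile(
        bee_type=bee_type,
        taxa={k: TaxonProfile(*v) for k, v in taxa.items()},
        gut_weight_mean_mg=gw_mean,
        gut_weight_sd_mg=gw_sd,
    )


def paper_anchors() -> dict[str, BeeTypeProfile]:
    """Default forager / nurse / winter profiles encoding the printed anchors."""
    forager = {
        "gilliamella": (6.8, 0.3, 1.0),
        "snodgrassella": (6.5, 0.3, 1.0),
        "bifidobacterium": (6.5, 0.3, 1.0),
        "lactobacillus_firm4": (6.3, 0.35, 0.984),
        "lactobacillus_firm5": (7.0, 0.3, 1.0),
        "frischella": (6.0, 0.55, 0.731),
        "bartonella": (5.8, 0.55, 0.947),
        # minor taxa (amplicon only)
        "commensalibacter": (5.8, 0.4, 1.0),
        "apibacter": (5.5, 0.4, 1.0),
        "lactobacillus_kunkeii": (5.0, 0.4, 0.5),
        "bombella": (4.8, 0.4, 0.4),
        "klebsiella": (4.8, 0.4, 0.1),
        "serratia": (4.6, 0.4, 0.1),
    }
    nurse = {
        "gilliamella": (6.8, 0.3, 1.0),
        "snodgrassella": (6.6, 0.3, 1.0),
        "bifidobacterium": (7.3, 0.3, 1.0),
        "lactobacillus_firm4": (7.3, 0.35, 0.984),
        "lactobacillus_firm5": (7.9, 0.3, 1.0),
        "frischella": (6.0, 0.55, 0.731),
        "bartonella": (6.3, 0.55, 0.947),
        "commensalibacter": (5.9, 0.4, 1.0),
        "apibacter": (5.5, 0.4, 1.0),
        "lactobacillus_kunkeii": (5.0, 0.4, 0.5),
        "bombella": (4.8, 0.4, 0.5),
        "klebsiella": (5.3, 0.4, 0.8),
        "serratia": (5.2, 0.4, 0.7),
    }
    # winter means solved so the analytic expected total-load ratio vs the
    # forager profile is ~10 (see module docstring)
    winter = {
        "gilliamella": (6.8, 0.3, 1.0),
        "snodgrassella": (6.7, 0.3, 1.0),
        "bifidobacterium": (7.5, 0.3, 1.0),
        "lactobacillus_firm4": (7.5, 0.35, 0.984),
        "lactobacillus_firm5": (8.17, 0.3, 1.0),
        "frischella": (5.3, 0.55, 0.731),
        "bartonella": (7.55, 0.45, 0.947),
        "commensalibacter": (7.2, 0.4, 1.0),
        "apibacter": (4.8, 0.4, 0.35),
        "lactobacillus_kunkeii": (5.0, 0.4, 0.0),
        "bombella": (4.5, 0.4, 0.15),
        "klebsiella": (4.5, 0.4, 0.05),
        "serratia": (4.3, 0.4, 0.05),
    }
    return {
        "forager": _profile("forager", forager, 30.0, 6.0),
        "nurse": _profile("nurse", nurse, 60.0, 10.0),
        "winter": _profile("winter", winter, 62.0, 10.0),
    }


@dataclass(frozen=True)
class ColonizationConfig:
    """Gnotobiotic colonization experiment: sugar water (SW) vs SW + pollen."""

    arms: Mapping[str, BeeTypeProfile]
    #: target rank correlation between gut weight and total bacterial load
    weight_load_spearman: float = 0.7

    def __post_init__(self) -> None:
        if not (-1.0 <= self.weight_load_spearman <= 1.0):
            raise ConfigError("weight_load_spearman must be in [-1,1]")


def colonization_anchors(weight_load_spearman: float = 0.7) -> ColonizationConfig:
    """Default SW vs SW+P arms.

    Anchors: Bartonella colonizes only 75% and Frischella under 50% of bees
    without pollen; pollen-fed guts are ~2x heavier; loads higher with pollen.
    """
    sw = {
        "gilliamella": (6.3, 0.45, 1.0),
        "snodgrassella": (6.3, 0.45, 1.0),
        "bifidobacterium": (6.2, 0.45, 1.0),
        "lactobacillus_firm4": (6.1, 0.45, 1.0),
        "lactobacillus_firm5": (6.5, 0.45, 1.0),
        "frischella": (5.3, 0.45, 0.45),
        "bartonella": (6.0, 0.45, 0.75),
    }
    swp = {
        "gilliamella": (6.9, 0.35, 1.0),
        "snodgrassella": (6.6, 0.35, 1.0),
        "bifidobacterium": (7.0, 0.35, 1.0),
        "lactobacillus_firm4": (6.9, 0.35, 1.0),
        "lactobacillus_firm5": (7.3, 0.35, 1.0),
        "frischella": (6.5, 0.35, 1.0),
        "bartonella": (6.2, 0.35, 1.0),
    }
    return ColonizationConfig(
        arms={
            "SW": _profile("SW", sw, 32.0, 6.0),
            "SW+P": _profile("SW+P", swp, 64.0, 10.0),
        },
        weight_load_spearman=weight_load_spearman,
    )
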