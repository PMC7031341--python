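"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`BeeQmpError`, so the CLI can abort
with the stage name and the underlying cause without a traceback.
"""


class BeeQmpError(Exception):
    """Base class for all package errors."""


class CalibrationError(BeeQmpError):
    """A standard curve is unusable (e.g. nonnegative slope)."""


class DegenerateCurveError(CalibrationError):
    """Fewer than three distinct dilution levels inside the included range."""


class SampleFailureError(BeeQmpError):
    """A gut sample cannot be normalized (actin amplification failed/missing)."""


class AnnotationError(BeeQmpError):
    """A taxon lacks a required annotation (phylotype, category, rRNA loci)."""


class DepthError(BeeQmpError):
    """A sample has zero sequencing depth after filtering."""


class DesignError(BeeQmpError):
    """Invalid statistical design (singleton group, too few groups...)."""


class ConfigError(BeeQmpError):
    """Invalid simulator or pipeline configuration."""


class LoadError(BeeQmpError):
    """A table on disk fails schema or invariant validation."""


class UndefinedStatisticError(DesignError):
    """A statistic is undefined on the input (e.g. constant vector)."""
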