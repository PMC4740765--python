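"""Exception hierarchy shared across the toolkit."""


class YstrError(Exception):
    """Base class for all toolkit errors."""


class AlleleFormatError(YstrError, ValueError):
    """An allele token could not be parsed."""


class SchemaError(YstrError, ValueError):
    """A haplotype table does not match the expected column schema."""


class ValidationError(YstrError, ValueError):
    """Input data violates a structural invariant (duplicate IDs, bad marginals...)."""


class ProjectionError(YstrError, ValueError):
    """Target panel is not a sub-panel of the source panel."""


class EstimatorError(YstrError, ValueError):
    """An estimator is undefined for the given sample size / spectrum."""


class EmptyComparisonError(YstrError, ValueError):
    """No loci remain after the missing-data exclusion policy."""


class DegreesOfFreedomError(YstrError, ValueError):
    """AMOVA design leaves no degrees of freedom."""


class NewickParseError(YstrError, ValueError):
    """Malformed Newick input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MarkerSelectionError(YstrError, ValueError):
    """Too few markers survive the exclusion rules."""


class ConfigError(YstrError, ValueError):
    """Invalid simulation or panel configuration."""


class SamplingError(YstrError, ValueError):
    """Cannot draw from an empty or invalid source."""
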