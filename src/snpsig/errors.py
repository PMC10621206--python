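"""Exception types shared across the package."""


class SnpsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SnpsigError):
    """An input file could not be parsed."""


class ValidationError(SnpsigError):
    """Input data violates a structural invariant (duplicate ids, bad states...)."""


class EmptyResultError(SnpsigError):
    """A filtering step removed everything; thresholds likely need review."""


class DegenerateDistributionError(SnpsigError):
    """A score distribution cannot support the quantile-based cohort rules."""


class UnsupportedOrderError(SnpsigError):
    """Expanded-genotype enumeration requested for a signature of more than 3 SNPs."""
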