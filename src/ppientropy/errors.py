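"""Exception hierarchy shared by all pipeline stages."""


class PipelineError(Exception):
    """Base class for every error this package raises on purpose."""


class ParseError(PipelineError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PipelineError):
    """Parsed data violates a documented invariant."""


class ResolutionError(ValidationError):
    """A cross-reference (sample id, accession) could not be resolved."""


class DegenerateDistributionError(PipelineError):
    """A distribution has no spread (all values identical, or all X equal)."""


class FitError(PipelineError):
    """The Gaussian bulk fit cannot be attempted (too few informative bins)."""


class EmptySubnetworkError(PipelineError):
    """Induction produced a graph with no edges for this patient."""
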