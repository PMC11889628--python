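"""Exception hierarchy shared across the pipeline stages."""


class ReadcovError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReadcovError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(ReadcovError, ValueError):
    """Invalid subject-level input (out-of-range percentile, unknown flag, ...)."""


class DesignError(ReadcovError, ValueError):
    """Rank-deficient or otherwise unusable regression design."""


class DegenerateRegionError(ReadcovError, ValueError):
    """A region has zero variance so a correlation is undefined."""


class DegenerateInputError(ReadcovError, ValueError):
    """Summary statistics that admit no test (e.g. zero pooled variance)."""


class GeometryError(ReadcovError, ValueError):
    """Image grids or affines that do not match or are unsupported."""


class FormatError(ReadcovError, ValueError):
    """A file whose contents violate the expected format."""
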