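"""Exception types shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class FcdegreeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FcdegreeError, ValueError):
    """A configuration value violates its contract (bad threshold, empty group, ...)."""


class DataError(FcdegreeError, ValueError):
    """Input data violate a precondition (shape mismatch, unusable subject, ...)."""
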