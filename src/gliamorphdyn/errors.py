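"""Exception hierarchy shared across the pipeline."""


class GliamorphError(Exception):
    """Base class for all package errors."""


class ConfigError(GliamorphError):
    """Invalid configuration or specification (CLI exit code 2)."""


class DataError(GliamorphError):
    """Invalid or unusable input data (CLI exit code 3)."""


class DegenerateInputError(DataError):
    """Input is formally valid but degenerate for the requested operation
    (all-zero volume, constant image, zero-variance differences, ...)."""
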