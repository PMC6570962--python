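"""Exception hierarchy for the pipeline."""


class PelletmorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PelletmorphError):
    """Invalid run configuration (bad paths, bad parameter values)."""


class NoInputError(ConfigurationError):
    """Image discovery matched zero files."""


class ImageIOError(PelletmorphError):
    """An image file could not be read or an output could not be written."""


class ContractViolation(PelletmorphError):
    """An internal geometric or numeric contract was broken."""


class ValidationError(PelletmorphError):
    """User-supplied data (QC flags, fractions) failed validation."""
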