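"""Exception hierarchy.

``ValidationError`` marks bad inputs/configuration (CLI exit code 2),
``ComputeError`` marks failures of the analysis itself (exit code 3).
"""


class LungDceError(Exception):
    """Base class for all package errors."""


class ValidationError(LungDceError, ValueError):
    """Invalid input data or configuration."""


class ComputeError(LungDceError, RuntimeError):
    """An analysis step failed on otherwise valid input."""


class DetectionError(ComputeError):
    """Bolus-arrival or AIF detection failed."""
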