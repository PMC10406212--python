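"""Exception hierarchy for the patchbleed pipeline.

Errors are grouped so the command line can map them onto distinct exit
codes: configuration problems, data/contract violations, and everything
else (runtime failures).
"""


class PatchbleedError(Exception):
    """Base class for all package errors."""


class ConfigError(PatchbleedError):
    """Invalid configuration value or schema violation."""


class DataError(PatchbleedError):
    """Input data violates a pipeline contract."""


class CoRegistrationError(DataError):
    """Volumes of one subject do not share grid shape/spacing."""


class DegenerateInputError(DataError):
    """Input is degenerate for the requested operation (e.g. a constant
    image cannot be linearly rescaled)."""
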