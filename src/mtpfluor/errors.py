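"""Exception hierarchy shared across the package."""


class MtpFluorError(Exception):
    """Base class for all package errors."""


class FormatError(MtpFluorError, ValueError):
    """A file or record violates the documented on-disk format."""


class GridError(MtpFluorError, ValueError):
    """Wavelength-grid mismatch or out-of-range request."""


class AlignmentError(MtpFluorError, ValueError):
    """Replicates or time bases that cannot be aligned."""


class ScheduleError(MtpFluorError, ValueError):
    """Conflicting or impossible sampling schedule."""


class IntegrationError(MtpFluorError, RuntimeError):
    """ODE integration produced a non-finite state."""


class ConfigError(MtpFluorError, ValueError):
    """Invalid run configuration."""
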