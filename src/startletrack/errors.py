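"""Exception types shared across the pipeline stages."""


class StartleTrackError(Exception):
    """Base class for all package errors."""


class ParameterError(StartleTrackError, ValueError):
    """A function argument violates its contract."""


class ConfigurationError(StartleTrackError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class FrameIOError(StartleTrackError, IOError):
    """A frame stack could not be read; the message names the offending frame."""


class CorruptStreamError(StartleTrackError, ValueError):
    """Embedded frame counters are non-monotone — the stack is corrupt."""


class DegeneratePathError(StartleTrackError, ValueError):
    """A centerline path is too short to resample."""


class DegenerateTableError(StartleTrackError, ValueError):
    """A contingency table has a zero row or column total."""
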