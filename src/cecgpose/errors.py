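"""Exception hierarchy used across the pipeline."""


class CecgError(Exception):
    """Base class for all package-specific errors."""


class ScheduleError(CecgError):
    """Posture schedule is overlapping, gapped, or otherwise invalid."""


class RateError(CecgError):
    """Sampling rate is invalid or timestamps are not uniform."""


class ParseError(CecgError):
    """A file could not be parsed; message carries line/field context."""


class ShapeError(CecgError):
    """Array or channel-count mismatch."""


class ParameterError(CecgError):
    """An operation parameter is out of its valid range."""


class InsufficientDataError(CecgError):
    """Too little data for the requested operation (e.g. < 2 R peaks)."""


class ProtocolError(CecgError):
    """Cross-validation protocol cannot be applied (e.g. < 2 subjects)."""


class DegenerateDataError(CecgError):
    """Training data is degenerate (e.g. a single class present)."""
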