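"""Exception hierarchy for the pipeline.

Degenerate inputs (all-negative PPG, too-short windows, all-missing blocks)
are signalled with dedicated exceptions so callers can decide whether to
drop a window, emit a missing estimate, or abort the session.
"""


class PulsetrackError(Exception):
    """Base class for all pulsetrack errors."""


class ConfigurationError(PulsetrackError):
    """A parameter value is outside its valid range."""


class DegenerateChannelError(PulsetrackError):
    """A channel cannot be processed (e.g. no positive samples, too short)."""


class InsufficientDataError(PulsetrackError):
    """Not enough samples / estimates to run the requested operation."""


class EmptyBlockError(PulsetrackError):
    """A tracking block contains no present heart-rate estimate."""


class EvaluationError(PulsetrackError):
    """Estimate and reference series cannot be compared (no overlap)."""
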