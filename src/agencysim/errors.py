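"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is invalid or non-finite."""


class ScheduleError(ValueError):
    """A visibility schedule is malformed (e.g. masks cover the whole trial)."""


class PacingError(ValueError):
    """Timing constants are inconsistent with beep pacing on sine extrema."""


class PoolError(ValueError):
    """The prerecorded-movement pool cannot satisfy a request."""


class InsufficientSamplesError(ValueError):
    """A scoring window contains no samples."""


class DegenerateVarianceError(ValueError):
    """A correlation input has zero variance."""
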