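"""Exception types shared across the pipeline."""


class VenoppgError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VenoppgError):
    """A parameter or configuration value is invalid (non-finite, out of range...)."""


class UninterpretableError(VenoppgError):
    """A recording (or one limb of it) cannot be analysed.

    Mirrors the clinical "uninterpretable recording" exclusion: too few
    detectable beats, an unusable rest window, an empty analysis window,
    or more than half of the heart-rate samples invalid.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
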