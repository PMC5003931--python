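"""Exception hierarchy shared across the package."""


class BiomusicError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BiomusicError):
    """A domain object violates one of its invariants."""


class MissingChannelError(BiomusicError):
    """A required physiological channel is absent from the recording."""

    def __init__(self, channel: str):
        self.channel = channel
        super().__init__(f"missing-channel: {channel!r} is required but absent")


class InsufficientSamplesError(BiomusicError):
    """The signal is too short for the requested operation."""


class NoBeatsError(BiomusicError):
    """No heartbeats could be detected in the blood-volume-pulse signal."""


class InsufficientBeatsError(BiomusicError):
    """Too few beats to form the requested sliding interbeat average."""


class NoBreathsError(BiomusicError):
    """No exhalation (peak-to-trough) pair could be found in the respiration signal."""


class NothingToSonifyError(BiomusicError):
    """All four feature series are absent; there is nothing to turn into music."""


class ConditionTooShortError(BiomusicError):
    """A condition label has no interval long enough for segment extraction."""

    def __init__(self, label: str, detail: str = ""):
        self.label = label
        msg = f"condition-too-short: no admissible window for label {label!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class UnscorableError(BiomusicError):
    """State-score validity cannot be assessed because a score is missing."""
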