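"""Exception hierarchy.

All package-specific errors derive from :class:`DevochronError` and from
``ValueError`` so that callers can catch either.
"""


class DevochronError(ValueError):
    """Base class for all devochron errors."""


class ConfigError(DevochronError):
    """Invalid configuration value (e.g. amplification efficiency <= 1)."""


class InvalidMeasurementError(DevochronError):
    """A Ct value is non-finite or non-positive."""


class GroupingError(DevochronError):
    """Technical replicates with mixed (gene, time, repeat) keys."""


class MissingSpikeInError(DevochronError):
    """A (time, repeat) sample lacks its spike-in rows."""


class InsufficientDataError(DevochronError):
    """Too few points/genes for the requested operation."""


class NonIdentifiableError(DevochronError):
    """Profile carries no signal the model could identify (e.g. all zeros)."""


class AlignmentError(DevochronError):
    """Cross-species time windows do not overlap after rescaling."""


class TableFormatError(DevochronError):
    """An input table is malformed or its dialect is ambiguous."""
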