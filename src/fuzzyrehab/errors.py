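"""Exception hierarchy shared across the package."""


class FuzzyRehabError(Exception):
    """Base class for all package errors."""


class DomainError(FuzzyRehabError):
    """A crisp value lies outside the universe of its linguistic variable."""


class ConfigurationError(FuzzyRehabError):
    """A fuzzy system or profile definition is internally inconsistent."""


class StateError(FuzzyRehabError):
    """An operation was applied to progress/session state out of order."""


class PatientSourceExhausted(FuzzyRehabError):
    """The event/stress source ran dry before the step terminated."""
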