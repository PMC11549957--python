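"""Exception hierarchy shared across the pipeline."""


class ReportfitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ReportfitError):
    """A parameter, column mapping, or config file is invalid."""


class InputError(ReportfitError):
    """The input data violate a corpus invariant (duplicate ids, no valid rows)."""


class ScoringError(ReportfitError):
    """A sentence could not be scored (e.g. empty after backend tokenization)."""


class BackendUnavailableError(ReportfitError):
    """A language-model backend's runtime dependencies or checkpoint are missing."""


class SizeError(ReportfitError):
    """An instance exceeds the size bound of an exhaustive routine."""
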