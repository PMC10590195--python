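"""Exception hierarchy shared across the pipeline."""


class TrawlkitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TrawlkitError, ValueError):
    """A value violates a domain precondition (non-positive length, bad weight...)."""


class InsufficientDataError(TrawlkitError, ValueError):
    """Too few or degenerate observations for a fit."""


class InconsistencyError(TrawlkitError, ValueError):
    """Two fields that must agree do not (e.g. subsample heavier than its fraction)."""


class GPXParseError(TrawlkitError, ValueError):
    """Malformed GPX document or trackpoint."""


class EmptyHaulError(TrawlkitError, ValueError):
    """Haul window does not overlap the GPS track."""


class ConfigError(TrawlkitError, ValueError):
    """Invalid configuration value (bin width, grid spec, mode...)."""


class MissingParameterError(TrawlkitError, KeyError):
    """A species lacks the length-weight parameters a conversion needs."""


class UnknownEntityError(TrawlkitError, KeyError):
    """A referenced species / haul / port is not in the dataset."""
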