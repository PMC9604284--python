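"""Exception hierarchy for colonytrack.

All exceptions derive from :class:`ColonyTrackError` so callers can catch the
package's failures with a single ``except`` clause; each subclass maps to one
contract family (file format, validation, unsupported input, missing data,
mathematical domain, configuration).
"""


class ColonyTrackError(Exception):
    """Base class for all colonytrack errors."""


class FormatError(ColonyTrackError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ColonyTrackError):
    """Input data violates a structural invariant (duplicates, bad labels...)."""


class UnsupportedFeatureError(ColonyTrackError):
    """The input uses a feature the reader deliberately does not support."""


class NotFoundError(ColonyTrackError):
    """A requested label/frame/group is absent from the data."""


class InsufficientDataError(ColonyTrackError):
    """Too few observations to compute the requested statistic."""


class DomainError(ColonyTrackError):
    """Arguments outside the mathematical domain of an operation."""


class ConfigError(ColonyTrackError):
    """Invalid configuration or parameterization."""


class EmptyInputError(ColonyTrackError):
    """An operation received an empty collection where data is required."""
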