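"""Exception hierarchy for limbkin.

All package errors derive from :class:`LimbkinError` so callers can catch
everything from one base class while the pipeline distinguishes configuration
mistakes from data-driven (geometry / statistics) failures.
"""


class LimbkinError(Exception):
    """Base class for all limbkin errors."""


class ConfigurationError(LimbkinError):
    """Invalid configuration: unknown task id, missing anthropometry field, ..."""


class DomainError(LimbkinError):
    """Argument outside its mathematical domain (fs <= 0, n_points < 2, ...)."""


class MissingMarkerError(LimbkinError):
    """A required marker or skeleton joint is absent from a trial."""


class DegenerateGeometryError(LimbkinError):
    """Collinear or coincident points make a frame construction singular."""


class SamplingError(LimbkinError):
    """Sampling-rate contract violated (Nyquist, unsupported downsampling, ...)."""


class SeriesLengthError(LimbkinError):
    """A series is too short for the requested operation."""


class UndefinedStatisticError(LimbkinError):
    """A statistic is undefined for the given data (zero variance, all-masked)."""


class PairingError(LimbkinError):
    """Trials or sessions cannot be matched for a paired analysis."""
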