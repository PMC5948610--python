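"""Exception hierarchy shared across the pipeline stages."""


class EcgIdError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EcgIdError):
    """A configuration value violates its contract (bad range, bad cutoff, ...)."""


class DegenerateBeatError(EcgIdError):
    """A requested beat is too short to render (< 10 samples)."""


class InsufficientCyclesError(EcgIdError):
    """A recording does not contain enough valid cardiac cycles."""


class InsufficientFiducialsError(EcgIdError):
    """A frame request exceeds the available fiducial points of a record."""


class SignalFormatError(EcgIdError):
    """An on-disk artifact is malformed (parse errors, missing sidecars, ...)."""
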