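"""Exception hierarchy shared across the pipeline."""


class SpinefatError(Exception):
    """Base class for all package-specific errors."""


class IncompleteSeriesError(SpinefatError):
    """A required channel of a Dixon series is missing."""


class GeometryMismatchError(SpinefatError):
    """Arrays or headers disagree on shape/spacing where they must match."""


class FormatError(SpinefatError):
    """A file could not be parsed in the expected imaging format."""


class ValidationError(SpinefatError):
    """A configuration or specification object violates its invariants."""


class DegenerateMaskError(SpinefatError):
    """A morphological operation annihilated a mask component."""
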