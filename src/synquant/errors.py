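"""Exception hierarchy shared across the quantification modules."""


class SynquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynquantError):
    """A required channel, role, or configuration key is missing or invalid."""


class ValidationError(SynquantError):
    """An input object violates a documented invariant."""


class FormatError(SynquantError):
    """A file's structure does not match the declared layout."""


class MetadataError(SynquantError):
    """Required metadata (typically the pixel size) cannot be resolved."""


class ParameterError(SynquantError):
    """An analysis parameter is outside its documented range."""


class PlacementError(SynquantError):
    """Synapses cannot be placed in the field at the requested spacing."""


class BoundaryError(SynquantError):
    """A measurement region exits the image bounds."""


class DegenerateInputError(SynquantError):
    """The input is degenerate for the requested operation (constant image,
    all-zero profile, empty ROI, all-zero paired differences, ...)."""
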