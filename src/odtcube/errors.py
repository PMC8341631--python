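"""Exception hierarchy for the ODT cube toolkit."""


class ODTError(Exception):
    """Base class for all toolkit errors."""


class CoordinateError(ODTError):
    """Latitude/longitude outside the valid WGS84 range."""


class HierarchyError(ODTError):
    """A place has no parent link on the requested roll-up path."""


class LevelError(ODTError):
    """Operation received data at an unexpected geographic level."""


class PlaceError(ODTError):
    """Unknown place identifier at the working level."""


class ConfigurationError(ODTError):
    """Mutually inconsistent or malformed configuration."""


class RecordError(ODTError):
    """A raw input record violates the format invariants."""


class BaselineError(ODTError):
    """Reduction-rate baseline period missing or has zero mass."""


class ExportError(ODTError):
    """Table does not match the flow CSV dialect schema."""


class FormatError(ODTError):
    """A file does not conform to the flow CSV dialect."""


class AvailabilityError(ODTError):
    """Requested (source, level) cube is not in the store."""


class EmptyInputError(ODTError):
    """Operation requires at least one element."""
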