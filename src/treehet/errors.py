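"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/format errors → 2,
data errors → 3, capacity errors → 4.
"""


class TreehetError(Exception):
    """Base class for all package errors."""


class FormatError(TreehetError, ValueError):
    """A file or structure does not conform to its documented format."""


class IntegrityError(TreehetError, ValueError):
    """Input violates a structural invariant (duplicate keys, asymmetry...)."""


class DataError(TreehetError, ValueError):
    """Input values make the requested computation undefined."""


class ConfigurationError(TreehetError, ValueError):
    """Configuration is inconsistent with the data or the schema."""


class CapacityError(TreehetError, RuntimeError):
    """Problem size exceeds the bounds of the requested algorithm."""


class MappingError(TreehetError, ValueError):
    """A tree mapping violates one of its defining constraints."""


class MeasureError(TreehetError, ValueError):
    """A measure cannot be normalized to a probability measure."""


class ScalingError(TreehetError, ValueError):
    """Height rescaling is undefined (e.g. all-zero heights)."""


class NewickParseError(FormatError):
    """Malformed Newick input; message carries the offending position."""
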