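"""Exception types shared across the package."""


class EntroselError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(EntroselError, ValueError):
    """Raised when an input violates a documented precondition."""


class InvalidArgumentError(EntroselError, ValueError):
    """Raised when a parameter is outside its documented domain."""


class DegenerateRoiError(EntroselError, ValueError):
    """Raised when a bounding box denormalizes to a crop smaller than 2x2 px."""


class InsufficientLengthError(EntroselError, ValueError):
    """Raised when a signal is too short for the requested measure."""


class RegistryError(EntroselError, KeyError):
    """Raised on lookup of an unknown feature id."""
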