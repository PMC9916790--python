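"""Exception hierarchy shared by all pipeline stages."""


class ThyromsiError(Exception):
    """Base class for all package errors."""


class ParameterError(ThyromsiError, ValueError):
    """A function argument is outside its documented domain."""


class InvariantError(ThyromsiError, ValueError):
    """A domain object violates one of its structural invariants."""


class ParseError(ThyromsiError, ValueError):
    """An input file is malformed; the message names the offending record."""


class ShapeError(ThyromsiError, ValueError):
    """Grid / mask / matrix dimensions disagree."""


class DataError(ThyromsiError, ValueError):
    """Input data are structurally valid but unusable for the operation."""


class ConfigError(ThyromsiError, ValueError):
    """A simulation or pipeline configuration is invalid."""
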