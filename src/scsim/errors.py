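"""Exception hierarchy for scsim."""


class ScsimError(Exception):
    """Base class for all scsim errors."""


class ConfigurationError(ScsimError, ValueError):
    """An experiment design is malformed or internally inconsistent."""


class DimensionError(ConfigurationError):
    """A vector or matrix in the design has the wrong shape."""


class RangeError(ConfigurationError):
    """A numeric parameter is outside its admissible range."""


class FormatError(ScsimError, ValueError):
    """An input file violates its declared format."""


class PoolExhaustedError(ScsimError, RuntimeError):
    """A bulk draw asked for more reads than a prototype pool holds.

    Carries the prototype index and the shortfall so the caller can
    regenerate a larger pool.
    """

    def __init__(self, prototype: int, requested: int, remaining: int):
        self.prototype = prototype
        self.requested = requested
        self.remaining = remaining
        super().__init__(
            f"read pool for prototype {prototype} exhausted: "
            f"requested {requested}, only {remaining} remaining"
        )
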