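"""Exception types shared across the package."""


class CargoQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CargoQuantError):
    """A simulation or analysis configuration violates its invariants."""


class InputError(CargoQuantError):
    """An input file or in-memory object does not conform to its schema."""


class UndefinedValueError(CargoQuantError):
    """A requested quantity is mathematically undefined for the given input."""
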