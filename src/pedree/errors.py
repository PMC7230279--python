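"""Exception hierarchy shared across the pipeline stages."""


class PedreeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PedreeError):
    """A configuration object violates its invariants."""


class InvalidMeasurementError(PedreeError):
    """A physical measurement is out of its physically meaningful domain."""


class OutOfReferenceError(PedreeError):
    """An age/sex/length falls outside the growth-reference table."""


class OutOfBandError(PedreeError):
    """No published coefficient band covers the (equation, sex, age)."""


class DegenerateVariableError(PedreeError):
    """A variable is constant (or otherwise unusable) where variation is required."""


class DataContractError(PedreeError):
    """A file or in-memory artifact does not match the documented contract."""
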