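"""Exception hierarchy shared by all goodph modules."""


class GoodPhError(Exception):
    """Base class for all goodph errors."""


class ValidationError(GoodPhError, ValueError):
    """Invalid input data or parameters."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line."""


class DegenerateInputError(ValidationError):
    """An input that makes the requested operation ill-posed."""


class OutOfRangeError(GoodPhError):
    """A result falls outside the probe's working range."""
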