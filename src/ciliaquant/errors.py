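"""Exception hierarchy shared by all ciliaquant modules."""


class CiliaQuantError(Exception):
    """Base class for all toolkit errors."""


class InputError(CiliaQuantError):
    """Invalid input data (shape, size, emptiness, missing fields)."""


class FormatError(CiliaQuantError):
    """A file could not be parsed in the expected format."""


class ParameterError(CiliaQuantError):
    """Invalid or mutually inconsistent parameter values."""


class NumericalError(CiliaQuantError):
    """A numerical routine failed to converge or hit a degenerate case."""
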