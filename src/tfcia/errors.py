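"""Typed exceptions so callers (and the CLI) can map failures to exit codes."""


class TfciaError(Exception):
    """Base class for all package errors."""


class ValidationError(TfciaError):
    """Invalid input data or configuration; message names the offending field/cell."""


class IOFormatError(TfciaError):
    """A file could not be read or written in the declared format."""


class NumericalError(TfciaError):
    """A computation is undefined for the given input (e.g. zero-inertia table)."""
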