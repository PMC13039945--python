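"""Typed exceptions used across the pipeline.

The CLI maps these onto distinct exit codes (usage errors are handled by
click itself): input/structural problems exit 3, numerical/undefined
results exit 4.
"""


class DffocmError(Exception):
    """Base class for all package errors."""


class ParameterError(DffocmError, ValueError):
    """A parameter violates its physical or structural constraints."""


class StructuralError(DffocmError, ValueError):
    """Array shapes or file structure are inconsistent."""


class DegenerateInputError(DffocmError, ValueError):
    """Input is technically well-formed but degenerate (e.g. a zero-mean frame)."""


class UndefinedResultError(DffocmError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input."""
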