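"""Exception hierarchy.

Readers and validators raise these instead of silently coercing; the CLI maps
input-side errors and configuration-side errors to distinct exit codes.
"""


class MatrixRnaiError(Exception):
    """Base class for all package errors."""


class FormatError(MatrixRnaiError):
    """Malformed input file: duplicates, non-numeric values, bad columns."""


class AnnotationError(MatrixRnaiError):
    """Sample-group annotation does not cover the expression matrix."""


class InputError(MatrixRnaiError):
    """Structurally valid input that violates an operation's precondition."""


class ParameterError(MatrixRnaiError):
    """Invalid parameter value (thresholds, ranges, counts)."""


class ConfigurationError(MatrixRnaiError):
    """Inconsistent run configuration (unknown keys, criteria without stats)."""
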